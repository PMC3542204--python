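"""Compiled Metropolis-coupled structure-MCMC kernel.

Graphs are held as per-node bitmasks (``children[u]`` has bit ``v`` set for
an edge u -> v, ``parents[v]`` mirrors it), which keeps acyclicity checks,
move enumeration and the Hastings neighbourhood counts cheap enough to run
the full tempered-chain protocol at the documented step counts.  Family
scores use the identical K2 closed form as :mod:`bnbmla.scoring` (asserted
by the test suite) and are memoised in a typed dict keyed on
``(node, parent-bitmask)``.

The bitmask representation caps the kernel at 62 variables; tag-SNP
reduction keeps realistic analyses well below that.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, types
from numba.typed import Dict

MAX_KERNEL_VARS = 62

ADD, DELETE, REVERSE = 0, 1, 2

_KEY = types.UniTuple(types.int64, 2)


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def _family_score(matrix, arities, node, pmask):
    """K2 log family score of ``node`` given the parent bitmask."""
    n, nv = matrix.shape
    r = arities[node]
    pars = np.empty(nv, np.int64)
    npar = 0
    q = 1
    for p in range(nv):
        if (pmask >> p) & 1:
            pars[npar] = p
            npar += 1
            q *= arities[p]
    counts = np.zeros(q * r, np.int64)
    for i in range(n):
        cfg = 0
        mult = 1
        for t in range(npar):
            p = pars[t]
            cfg += matrix[i, p] * mult
            mult *= arities[p]
        counts[cfg * r + matrix[i, node]] += 1
    total = 0.0
    lg_r = math.lgamma(r)
    for j in range(q):
        nj = 0
        for k in range(r):
            nj += counts[j * r + k]
        if nj > 0:
            total += lg_r - math.lgamma(r + nj)
            for k in range(r):
                c = counts[j * r + k]
                if c > 1:
                    total += math.lgamma(1.0 + c)
    return total


@njit(cache=True)
def _family_cached(matrix, arities, node, pmask, cache):
    key = (np.int64(node), np.int64(pmask))
    if key in cache:
        return cache[key]
    v = _family_score(matrix, arities, node, pmask)
    cache[key] = v
    return v


@njit(cache=True)
def _closure(children, n):
    """Descendant bitmasks (paths of length >= 1)."""
    reach = children.copy()
    changed = True
    while changed:
        changed = False
        for u in range(n):
            acc = reach[u]
            m = reach[u]
            v = 0
            while m:
                if m & 1:
                    acc |= reach[v]
                m >>= 1
                v += 1
            if acc != reach[u]:
                reach[u] = acc
                changed = True
    return reach


@njit(cache=True)
def _enumerate_moves(children, parents, reach, n, maxp, kinds, us, vs):
    """All acyclicity- and in-degree-preserving single-edge moves."""
    cnt = 0
    one = np.int64(1)
    for u in range(n):
        cu = children[u]
        for v in range(n):
            if u == v:
                continue
            if (cu >> v) & 1:
                kinds[cnt] = DELETE
                us[cnt] = u
                vs[cnt] = v
                cnt += 1
                # reverse u->v: u gains parent v; invalid if an alternative
                # (length >= 2) path u ~> v exists or u is at the parent cap
                if _popcount(parents[u]) < maxp:
                    alt = False
                    m = cu & ~(one << v)
                    x = 0
                    while m:
                        if m & 1:
                            if (reach[x] >> v) & 1:
                                alt = True
                                break
                        m >>= 1
                        x += 1
                    if not alt:
                        kinds[cnt] = REVERSE
                        us[cnt] = u
                        vs[cnt] = v
                        cnt += 1
            else:
                # add u->v: cycle iff v already reaches u
                if _popcount(parents[v]) < maxp and not ((reach[v] >> u) & 1):
                    kinds[cnt] = ADD
                    us[cnt] = u
                    vs[cnt] = v
                    cnt += 1
    return cnt


@njit(cache=True)
def _count_moves(children, parents, reach, n, maxp):
    cnt = 0
    one = np.int64(1)
    for u in range(n):
        cu = children[u]
        for v in range(n):
            if u == v:
                continue
            if (cu >> v) & 1:
                cnt += 1
                if _popcount(parents[u]) < maxp:
                    alt = False
                    m = cu & ~(one << v)
                    x = 0
                    while m:
                        if m & 1:
                            if (reach[x] >> v) & 1:
                                alt = True
                                break
                        m >>= 1
                        x += 1
                    if not alt:
                        cnt += 1
            else:
                if _popcount(parents[v]) < maxp and not ((reach[v] >> u) & 1):
                    cnt += 1
    return cnt


@njit(cache=True)
def run_mc3_kernel(
    matrix,
    arities,
    maxp,
    betas,
    burn_in,
    n_steps,
    thinning,
    swap_interval,
    seed,
    prior_parent_size,
    logc,
):
    """Run one MC3 replicate; returns cold-chain parent-mask samples.

    ``betas`` is the inverse-temperature ladder, cold chain first
    (``betas[0] == 1``).  ``prior_parent_size`` switches the structure prior
    from uniform-over-DAGs (0) to the parent-set-cardinality prior whose
    per-size log weights are in ``logc``.  Samples are parent bitmasks of
    the cold chain, one row per thinned post-burn-in step.
    """
    np.random.seed(seed)
    n = matrix.shape[1]
    nc = betas.shape[0]
    one = np.int64(1)

    children = np.zeros((nc, n), np.int64)
    parents = np.zeros((nc, n), np.int64)
    scores = np.zeros(nc)
    priors = np.zeros(nc)
    cache = Dict.empty(key_type=_KEY, value_type=types.float64)

    empty_total = 0.0
    for v in range(n):
        empty_total += _family_cached(matrix, arities, v, 0, cache)
    for c in range(nc):
        scores[c] = empty_total
        priors[c] = 0.0  # empty graph: all parent sets size 0, logc[0] = 0

    n_rec = n_steps // thinning
    rec = np.zeros((n_rec, n), np.int64)
    accepts = np.zeros(nc, np.int64)
    proposals = np.zeros(nc, np.int64)
    swap_accepts = 0
    swap_proposals = 0

    kinds = np.empty(3 * n * n, np.int64)
    us = np.empty(3 * n * n, np.int64)
    vs = np.empty(3 * n * n, np.int64)

    total_steps = burn_in + n_steps
    ri = 0
    for step in range(total_steps):
        for c in range(nc):
            reach = _closure(children[c], n)
            m1 = _enumerate_moves(children[c], parents[c], reach, n, maxp, kinds, us, vs)
            if m1 == 0:
                continue
            proposals[c] += 1
            k = np.random.randint(m1)
            kind = kinds[k]
            u = us[k]
            v = vs[k]

            d_score = 0.0
            d_prior = 0.0
            if kind == ADD:
                pv_old = parents[c, v]
                pv_new = pv_old | (one << u)
                d_score = _family_cached(matrix, arities, v, pv_new, cache) - _family_cached(
                    matrix, arities, v, pv_old, cache
                )
                if prior_parent_size:
                    sz = _popcount(pv_old)
                    d_prior = logc[sz + 1] - logc[sz]
                children[c, u] |= one << v
                parents[c, v] = pv_new
            elif kind == DELETE:
                pv_old = parents[c, v]
                pv_new = pv_old & ~(one << u)
                d_score = _family_cached(matrix, arities, v, pv_new, cache) - _family_cached(
                    matrix, arities, v, pv_old, cache
                )
                if prior_parent_size:
                    sz = _popcount(pv_old)
                    d_prior = logc[sz - 1] - logc[sz]
                children[c, u] &= ~(one << v)
                parents[c, v] = pv_new
            else:  # REVERSE u->v  =>  delete u->v, add v->u
                pv_old = parents[c, v]
                pu_old = parents[c, u]
                pv_new = pv_old & ~(one << u)
                pu_new = pu_old | (one << v)
                d_score = (
                    _family_cached(matrix, arities, v, pv_new, cache)
                    + _family_cached(matrix, arities, u, pu_new, cache)
                    - _family_cached(matrix, arities, v, pv_old, cache)
                    - _family_cached(matrix, arities, u, pu_old, cache)
                )
                if prior_parent_size:
                    d_prior = (
                        logc[_popcount(pv_new)]
                        + logc[_popcount(pu_new)]
                        - logc[_popcount(pv_old)]
                        - logc[_popcount(pu_old)]
                    )
                children[c, u] &= ~(one << v)
                children[c, v] |= one << u
                parents[c, v] = pv_new
                parents[c, u] = pu_new

            reach2 = _closure(children[c], n)
            m2 = _count_moves(children[c], parents[c], reach2, n, maxp)
            delta = d_score + d_prior
            log_alpha = betas[c] * delta + math.log(m1) - math.log(m2)
            if log_alpha >= 0.0 or math.log(np.random.random()) < log_alpha:
                accepts[c] += 1
                scores[c] += d_score
                priors[c] += d_prior
            else:
                # revert
                if kind == ADD:
                    children[c, u] &= ~(one << v)
                    parents[c, v] &= ~(one << u)
                elif kind == DELETE:
                    children[c, u] |= one << v
                    parents[c, v] |= one << u
                else:
                    children[c, u] |= one << v
                    children[c, v] &= ~(one << u)
                    parents[c, v] |= one << u
                    parents[c, u] &= ~(one << v)

        if swap_interval > 0 and nc > 1 and (step + 1) % swap_interval == 0:
            i = np.random.randint(nc - 1)
            j = i + 1
            swap_proposals += 1
            si = scores[i] + priors[i]
            sj = scores[j] + priors[j]
            log_alpha = (betas[i] - betas[j]) * (sj - si)
            if log_alpha >= 0.0 or math.log(np.random.random()) < log_alpha:
                swap_accepts += 1
                for t in range(n):
                    children[i, t], children[j, t] = children[j, t], children[i, t]
                    parents[i, t], parents[j, t] = parents[j, t], parents[i, t]
                scores[i], scores[j] = scores[j], scores[i]
                priors[i], priors[j] = priors[j], priors[i]

        if step >= burn_in and (step - burn_in + 1) % thinning == 0 and ri < n_rec:
            for t in range(n):
                rec[ri, t] = parents[0, t]
            ri += 1

    return rec, accepts, proposals, swap_accepts, swap_proposals, scores
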