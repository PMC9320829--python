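"""Structured-coalescent simulation and branch-length expected SFS.

The engine realises genealogies of a :class:`~antdiv.demography.DemographicModel`
under the standard structured coalescent: within a deme of haploid size
``N``, ``k`` lineages coalesce at total rate ``k(k-1)/(2N)`` per
generation; each lineage in deme ``i`` migrates (backward in time) to
deme ``j`` at rate ``m[i][j]``.  Waiting times between events are
exponential (continuous-time approximation) and demographic events are
applied at their scheduled times.

The expected joint site frequency spectrum is approximated by the
branch-length method: each branch contributes its length (in
generations) to the unfolded entry given by its number of descendant
sample copies in each of the two sampled demes; with an infinite-sites
per-site mutation rate ``mu``, the probability that a random site shows
a given configuration is ``mu`` times the mean contributed length, and
the monomorphic probability is one minus ``mu`` times the mean total
tree length.  This is linear in ``mu`` and only valid while
``mu * E[total length] < 1``.

Seed contract: every public function takes one integer seed; a call is
bit-reproducible on a platform.  Replicate ``r`` of a multi-genealogy
call consumes a documented sequential substream of the generator seeded
once at entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .demography import DemographicModel

__all__ = [
    "MU",
    "GENERATION_TIME_YEARS",
    "Genealogy",
    "ExpectedSFS",
    "NonCoalescingError",
    "simulate_genealogy",
    "simulate_genealogies",
    "expected_sfs",
    "fold_joint",
]

#: Per-site per-generation mutation rate used throughout (social-insect
#: estimate for *Formica*-group genomes).
MU = 3.5e-9

#: Queen generation time in years (overlapping generations, queens
#: living up to ~5 years).
GENERATION_TIME_YEARS = 2.5

_MAX_STEPS = 50_000_000


class NonCoalescingError(RuntimeError):
    """Raised when the sample cannot reach a common ancestor (e.g. zero
    migration between demes that are never joined)."""


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------


@njit(cache=True)
def _expected_sfs_kernel(
    sizes0,
    mig0,
    ev_time,
    ev_type,
    ev_a,
    ev_b,
    ev_size,
    mig_stack,
    samples,
    n_genealogies,
    seed,
):
    """Accumulate branch lengths into the unfolded joint-SFS grid.

    Returns ``(A, total_length_sum, err)`` where ``A[i, j]`` is the summed
    length (over genealogies) of branches with ``i`` descendant copies in
    deme 0 and ``j`` in deme 1, and ``err`` is 1 for a non-coalescing
    configuration.
    """
    np.random.seed(seed)
    D = sizes0.shape[0]
    n1 = samples[0]
    n2 = samples[1] if D > 1 else 0
    ntot = 0
    for d in range(D):
        ntot += samples[d]
    A = np.zeros((n1 + 1, n2 + 1))
    Lsum = 0.0
    sizes = sizes0.copy()
    mig = mig0.copy()
    ldeme = np.empty(ntot, np.int64)
    l1 = np.empty(ntot, np.int64)
    l2 = np.empty(ntot, np.int64)
    cnt = np.zeros(D, np.int64)
    n_ev = ev_time.shape[0]
    err = 0
    for _g in range(n_genealogies):
        for d in range(D):
            sizes[d] = sizes0[d]
            cnt[d] = samples[d]
            for j in range(D):
                mig[d, j] = mig0[d, j]
        idx = 0
        for d in range(D):
            for _s in range(samples[d]):
                ldeme[idx] = d
                l1[idx] = 1 if d == 0 else 0
                l2[idx] = 1 if d == 1 else 0
                idx += 1
        k = ntot
        t = 0.0
        ei = 0
        steps = 0
        while k > 1:
            steps += 1
            if steps > _MAX_STEPS:
                err = 1
                break
            coal_tot = 0.0
            for d in range(D):
                coal_tot += cnt[d] * (cnt[d] - 1) / (2.0 * sizes[d])
            mig_tot = 0.0
            for d in range(D):
                if cnt[d] > 0:
                    row = 0.0
                    for j in range(D):
                        row += mig[d, j]
                    mig_tot += cnt[d] * row
            R = coal_tot + mig_tot
            nev_t = ev_time[ei] if ei < n_ev else np.inf
            if R <= 0.0:
                if nev_t == np.inf:
                    err = 1
                    break
                dt = np.inf
            else:
                dt = np.random.exponential(1.0 / R)
            if t + dt >= nev_t:
                seg = nev_t - t
                if seg > 0.0:
                    for i in range(k):
                        A[l1[i], l2[i]] += seg
                    Lsum += k * seg
                t = nev_t
                typ = ev_type[ei]
                if typ == 0:  # join: source ev_a into dest ev_b
                    src = ev_a[ei]
                    dst = ev_b[ei]
                    for i in range(k):
                        if ldeme[i] == src:
                            ldeme[i] = dst
                    cnt[dst] += cnt[src]
                    cnt[src] = 0
                    for j in range(D):
                        mig[src, j] = 0.0
                        mig[j, src] = 0.0
                elif typ == 1:  # resize
                    sizes[ev_a[ei]] = ev_size[ei]
                else:  # set migration matrix
                    mi = ev_a[ei]
                    for d in range(D):
                        for j in range(D):
                            mig[d, j] = mig_stack[mi, d, j]
                ei += 1
            else:
                for i in range(k):
                    A[l1[i], l2[i]] += dt
                Lsum += k * dt
                t += dt
                u = np.random.random() * R
                chosen = -1  # deme for coalescence
                for d in range(D):
                    cr = cnt[d] * (cnt[d] - 1) / (2.0 * sizes[d])
                    if u < cr:
                        chosen = d
                        break
                    u -= cr
                if chosen >= 0:
                    # pick an unordered pair uniformly within deme `chosen`
                    a = int(np.random.random() * cnt[chosen])
                    b = int(np.random.random() * (cnt[chosen] - 1))
                    if b >= a:
                        b += 1
                    ia = -1
                    ib = -1
                    seen = 0
                    for i in range(k):
                        if ldeme[i] == chosen:
                            if seen == a:
                                ia = i
                            if seen == b:
                                ib = i
                            seen += 1
                    if ib < ia:
                        ia, ib = ib, ia
                    l1[ia] += l1[ib]
                    l2[ia] += l2[ib]
                    # compact: move the last lineage into slot ib
                    ldeme[ib] = ldeme[k - 1]
                    l1[ib] = l1[k - 1]
                    l2[ib] = l2[k - 1]
                    k -= 1
                    cnt[chosen] -= 1
                else:
                    # migration event
                    done = False
                    for d in range(D):
                        if done:
                            break
                        for j in range(D):
                            r = cnt[d] * mig[d, j]
                            if u < r:
                                pick = int(np.random.random() * cnt[d])
                                seen = 0
                                for i in range(k):
                                    if ldeme[i] == d:
                                        if seen == pick:
                                            ldeme[i] = j
                                            break
                                        seen += 1
                                cnt[d] -= 1
                                cnt[j] += 1
                                done = True
                                break
                            u -= r
                    # floating-point slack: if nothing selected, redraw
        if err == 1:
            break
    return A, Lsum, err


@njit(cache=True)
def _genealogy_kernel(
    sizes0,
    mig0,
    ev_time,
    ev_type,
    ev_a,
    ev_b,
    ev_size,
    mig_stack,
    samples,
    seed,
):
    """Simulate one genealogy, recording topology.

    Returns ``(parent, node_time, leaf_deme, err)``; nodes ``0..n-1`` are
    leaves in deme order, internal nodes are appended in coalescence
    order, the root is node ``2n-2``.
    """
    np.random.seed(seed)
    D = sizes0.shape[0]
    ntot = 0
    for d in range(D):
        ntot += samples[d]
    n_nodes = 2 * ntot - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes, np.float64)
    leaf_deme = np.empty(ntot, np.int64)
    sizes = sizes0.copy()
    mig = mig0.copy()
    ldeme = np.empty(ntot, np.int64)
    lnode = np.empty(ntot, np.int64)
    cnt = np.zeros(D, np.int64)
    idx = 0
    for d in range(D):
        cnt[d] = samples[d]
        for _s in range(samples[d]):
            ldeme[idx] = d
            leaf_deme[idx] = d
            lnode[idx] = idx
            idx += 1
    n_ev = ev_time.shape[0]
    next_node = ntot
    k = ntot
    t = 0.0
    ei = 0
    steps = 0
    err = 0
    while k > 1:
        steps += 1
        if steps > _MAX_STEPS:
            err = 1
            break
        coal_tot = 0.0
        for d in range(D):
            coal_tot += cnt[d] * (cnt[d] - 1) / (2.0 * sizes[d])
        mig_tot = 0.0
        for d in range(D):
            if cnt[d] > 0:
                row = 0.0
                for j in range(D):
                    row += mig[d, j]
                mig_tot += cnt[d] * row
        R = coal_tot + mig_tot
        nev_t = ev_time[ei] if ei < n_ev else np.inf
        if R <= 0.0:
            if nev_t == np.inf:
                err = 1
                break
            dt = np.inf
        else:
            dt = np.random.exponential(1.0 / R)
        if t + dt >= nev_t:
            t = nev_t
            typ = ev_type[ei]
            if typ == 0:
                src = ev_a[ei]
                dst = ev_b[ei]
                for i in range(k):
                    if ldeme[i] == src:
                        ldeme[i] = dst
                cnt[dst] += cnt[src]
                cnt[src] = 0
                for j in range(D):
                    mig[src, j] = 0.0
                    mig[j, src] = 0.0
            elif typ == 1:
                sizes[ev_a[ei]] = ev_size[ei]
            else:
                mi = ev_a[ei]
                for d in range(D):
                    for j in range(D):
                        mig[d, j] = mig_stack[mi, d, j]
            ei += 1
        else:
            t += dt
            u = np.random.random() * R
            chosen = -1
            for d in range(D):
                cr = cnt[d] * (cnt[d] - 1) / (2.0 * sizes[d])
                if u < cr:
                    chosen = d
                    break
                u -= cr
            if chosen >= 0:
                a = int(np.random.random() * cnt[chosen])
                b = int(np.random.random() * (cnt[chosen] - 1))
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(k):
                    if ldeme[i] == chosen:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
                if ib < ia:
                    ia, ib = ib, ia
                parent[lnode[ia]] = next_node
                parent[lnode[ib]] = next_node
                node_time[next_node] = t
                lnode[ia] = next_node
                next_node += 1
                ldeme[ib] = ldeme[k - 1]
                lnode[ib] = lnode[k - 1]
                k -= 1
                cnt[chosen] -= 1
            else:
                done = False
                for d in range(D):
                    if done:
                        break
                    for j in range(D):
                        r = cnt[d] * mig[d, j]
                        if u < r:
                            pick = int(np.random.random() * cnt[d])
                            seen = 0
                            for i in range(k):
                                if ldeme[i] == d:
                                    if seen == pick:
                                        ldeme[i] = j
                                        break
                                    seen += 1
                            cnt[d] -= 1
                            cnt[j] += 1
                            done = True
                            break
                        u -= r
    return parent, node_time, leaf_deme, err


# ----------------------------------------------------------------------
# public types
# ----------------------------------------------------------------------


@dataclass
class Genealogy:
    """A realised binary genealogy over the sampled haploid lineages.

    Nodes ``0..n_leaves-1`` are leaves (in deme order of the model);
    internal nodes follow in coalescence order; ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    leaf_deme: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.leaf_deme.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        bl[nz] = self.node_time[self.parent[nz]] - self.node_time[nz]
        return bl

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def descendant_matrix(self) -> np.ndarray:
        """Boolean ``(n_nodes, n_leaves)``: leaf ``l`` descends from node ``v``."""
        n, nn = self.n_leaves, self.n_nodes
        M = np.zeros((nn, n), dtype=bool)
        M[np.arange(n), np.arange(n)] = True
        # children have smaller indices than parents by construction
        for v in range(nn - 1):
            p = self.parent[v]
            if p >= 0:
                M[p] |= M[v]
        return M


@dataclass
class ExpectedSFS:
    """Branch-length approximation of the expected joint SFS.

    ``probs[i, j]`` is the probability that a random site carries a
    mutation with ``i`` derived copies among deme-0 samples and ``j``
    among deme-1 samples; ``p_mono`` the probability of no mutation.
    Entries sum to 1 by construction.
    """

    probs: np.ndarray
    p_mono: float
    n1: int
    n2: int
    n_genealogies: int
    mu: float
    mean_total_length: float

    def check(self, tol: float = 1e-12) -> None:
        total = float(self.probs.sum()) + self.p_mono
        if abs(total - 1.0) > tol:
            raise AssertionError(f"probabilities sum to {total}, not 1")
        if (self.probs < 0).any() or self.p_mono < 0:
            raise AssertionError("negative probability")

    def folded(self) -> np.ndarray:
        """Fold onto the pooled minor-allele domain (see :func:`fold_joint`)."""
        return fold_joint(self.probs)


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------


def _kernel_seed(rng_seed: int) -> int:
    return int(np.uint32(rng_seed & 0xFFFFFFFF))


def simulate_genealogy(model: DemographicModel, rng_seed: int) -> Genealogy:
    """Draw one structured-coalescent genealogy; deterministic given seed."""
    if model.n_samples < 2:
        raise ValueError("total sample size must be >= 2")
    enc = model.encode()
    parent, node_time, leaf_deme, err = _genealogy_kernel(*enc, _kernel_seed(rng_seed))
    if err:
        raise NonCoalescingError(
            "sample cannot reach a common ancestor under this model "
            "(no migration path between never-joined demes?)"
        )
    return Genealogy(parent=parent, node_time=node_time, leaf_deme=leaf_deme)


def simulate_genealogies(model: DemographicModel, n: int, rng_seed: int):
    """Yield ``n`` independent genealogies from a documented substream.

    Replicate ``r`` uses the ``r``-th word of the stream generated by
    ``numpy.random.SeedSequence(rng_seed)``.
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(n)
    for r in range(n):
        yield simulate_genealogy(model, int(seeds[r]))


def expected_sfs(
    model: DemographicModel,
    n_genealogies: int,
    rng_seed: int,
    mu: float = MU,
) -> ExpectedSFS:
    """Monte-Carlo expected joint SFS via the branch-length method."""
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be >= 1")
    if model.n_samples < 2:
        raise ValueError("total sample size must be >= 2")
    enc = model.encode()
    A, Lsum, err = _expected_sfs_kernel(*enc, n_genealogies, _kernel_seed(rng_seed))
    if err:
        raise NonCoalescingError(
            "sample cannot reach a common ancestor under this model"
        )
    mean_len = Lsum / n_genealogies
    poly_mass = mu * mean_len
    if poly_mass >= 1.0:
        raise ValueError(
            f"mu * E[total length] = {poly_mass:.3g} >= 1: mutation rate or "
            "population sizes outside the linear infinite-sites regime"
        )
    probs = (mu / n_genealogies) * A
    samples = model.sample_sizes()
    n1 = samples[0]
    n2 = samples[1] if len(samples) > 1 else 0
    return ExpectedSFS(
        probs=probs,
        p_mono=1.0 - poly_mass,
        n1=n1,
        n2=n2,
        n_genealogies=n_genealogies,
        mu=mu,
        mean_total_length=mean_len,
    )


def fold_joint(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint spectrum onto the pooled minor-allele domain.

    Entry ``(i, j)`` with ``i + j > (n1 + n2) / 2`` is added to its mirror
    ``(n1 - i, n2 - j)``.  Exact ties ``i + j == (n1 + n2) / 2`` are mapped
    to the member of the pair with the smaller first coordinate (smaller
    second coordinate if the first coordinates tie); split weights are not
    used.  Folding an already folded spectrum is the identity.
    """
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    half = (n1 + n2) / 2.0
    out = np.zeros_like(unfolded, dtype=np.float64)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            v = unfolded[i, j]
            if v == 0:
                continue
            tot = i + j
            if tot < half:
                out[i, j] += v
            elif tot > half:
                out[n1 - i, n2 - j] += v
            else:  # tie: canonical representative
                mi, mj = n1 - i, n2 - j
                if (i, j) <= (mi, mj):
                    out[i, j] += v
                else:
                    out[mi, mj] += v
    return out
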