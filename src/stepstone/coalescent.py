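"""Structured-coalescent simulation of genealogies and site-frequency spectra.

Each locus is a single non-recombining site.  A genealogy is simulated
backward in time under the structured coalescent with the demography's
event program (splits, admixture pulses, migration and size changes); the
quantity recorded per branch is the vector of sampled-leaf counts it
subtends in each population, which is all that mutations need.

Mutation models (infinite sites):

* ``simulate_sfs`` places Poisson(mu * branch length) mutations on each
  locus's genealogy and accumulates them into a joint SFS; loci without
  mutations contribute nothing (they are the monomorphic mass).
* ``simulate_snp_sfs`` returns a spectrum with an exact number of
  segregating sites.  In the small-mu limit, conditioning a locus on being
  polymorphic weights its genealogy by total branch length and places one
  mutation uniformly on it; pooling branch lengths over many simulated
  genealogies and drawing the requested number of sites multinomially is
  the same process, so that is what is implemented.
* ``expected_sfs_probs`` estimates the per-SNP probability of each joint
  SFS cell as (pooled branch length subtending that cell) / (pooled total
  length) -- the Monte-Carlo expectation used by the composite likelihood.

Seeding: one root seed; per-locus generators are derived with a
counter-based ``SeedSequence`` splitter, so results are independent of any
batching of loci.
"""

from __future__ import annotations

import math
import random
from typing import Iterator

import numpy as np

from .demography import Demography
from .sfs import SFS

__all__ = [
    "CoalescenceError",
    "simulate_branches",
    "simulate_sfs",
    "simulate_snp_sfs",
    "expected_sfs_probs",
    "sfs_shape",
]

_MULTINOMIAL_KEY = 2**30 + 1  # reserved spawn key for the site-placement draw


class CoalescenceError(RuntimeError):
    """The coalescent failed to reach a common ancestor (disconnected demes
    or the per-locus event cap was exceeded)."""


def locus_rng(seed: int, locus: int) -> random.Random:
    """Deterministic per-locus stream derived from one root seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(locus,))
    return random.Random(int(ss.generate_state(2, np.uint64)[0]))


def sfs_shape(demog: Demography) -> tuple[int, ...]:
    return tuple(2 * d.n_samples + 1 for d in demog.demes if d.n_samples > 0)


def _prepare(demog: Demography):
    """Resolve labels to indices once per demography."""
    labels = demog.labels
    idx = demog.index
    sizes = np.array([d.Ne for d in demog.demes], dtype=float)
    mig = np.asarray(demog.migration0, dtype=float).copy()
    sampled = [i for i, d in enumerate(demog.demes) if d.n_samples > 0]
    events = []
    for ev in demog.events:
        events.append(
            (
                ev.time,
                ev.kind,
                idx[ev.source] if ev.source else -1,
                idx[ev.dest] if ev.dest else -1,
                ev.fraction,
                ev.size,
                None if ev.matrix is None else np.asarray(ev.matrix, dtype=float),
            )
        )
    return labels, sizes, mig, sampled, events


def simulate_branches(
    demog: Demography,
    rng: random.Random,
    max_steps: int = 1_000_000,
    track_leaves: bool = False,
    _prep=None,
):
    """Simulate one genealogy; return a list of branches.

    Each branch is ``(config, length)`` where ``config`` is the tuple of
    per-sampled-population leaf counts the branch subtends (or, with
    ``track_leaves``, an integer bitmask over haploid sample indices).
    The branch above the root is not included.
    """
    labels, sizes0, mig0, sampled, events = _prep or _prepare(demog)
    sizes = sizes0.copy()
    mig = mig0.copy()
    npop = len(labels)
    naxes = len(sampled)
    axis_of = {p: a for a, p in enumerate(sampled)}

    # lineages: parallel lists of deme index, config, birth time
    deme_of: list[int] = []
    config: list = []
    born: list[float] = []
    leaf = 0
    for a, p in enumerate(sampled):
        k = 2 * demog.demes[p].n_samples
        for _ in range(k):
            deme_of.append(p)
            if track_leaves:
                config.append(1 << leaf)
                leaf += 1
            else:
                c = [0] * naxes
                c[a] = 1
                config.append(tuple(c))
            born.append(0.0)
    n = len(deme_of)
    if n < 2:
        raise CoalescenceError("need at least two sampled lineages")

    branches = []
    t = 0.0
    ei = 0
    row_sum = mig.sum(axis=1)
    counts = [0] * npop
    for d in deme_of:
        counts[d] += 1
    steps = 0
    expo = rng.expovariate
    unif = rng.random

    while n > 1:
        steps += 1
        if steps > max_steps:
            raise CoalescenceError(
                f"no common ancestor after {max_steps} events; "
                "demography may leave demes disconnected"
            )
        coal = 0.0
        for d in range(npop):
            k = counts[d]
            if k > 1:
                coal += k * (k - 1) / (4.0 * sizes[d])
        migr = 0.0
        for d in range(npop):
            if counts[d]:
                migr += counts[d] * row_sum[d]
        total = coal + migr
        t_next = events[ei][0] if ei < len(events) else math.inf
        if total <= 0.0:
            if math.isinf(t_next):
                raise CoalescenceError(
                    "all rates zero with multiple lineages remaining "
                    "(disconnected demes with no further events)"
                )
            t = t_next
        else:
            dt = expo(total)
            if t + dt >= t_next:
                t = t_next
            else:
                t += dt
                u = unif() * total
                if u < coal:
                    # pick deme by coalescence weight, then a random pair
                    acc = 0.0
                    d = -1
                    for dd in range(npop):
                        k = counts[dd]
                        if k > 1:
                            d = dd
                            acc += k * (k - 1) / (4.0 * sizes[dd])
                            if u < acc:
                                break
                    i1, i2 = _pick_pair(deme_of, counts[d], d, rng)
                    branches.append((config[i1], t - born[i1]))
                    branches.append((config[i2], t - born[i2]))
                    if track_leaves:
                        config[i1] = config[i1] | config[i2]
                    else:
                        config[i1] = tuple(map(sum, zip(config[i1], config[i2])))
                    born[i1] = t
                    # remove i2 by swap-pop
                    last = len(deme_of) - 1
                    counts[d] -= 1
                    if i2 != last:
                        deme_of[i2] = deme_of[last]
                        config[i2] = config[last]
                        born[i2] = born[last]
                    deme_of.pop()
                    config.pop()
                    born.pop()
                    n -= 1
                else:
                    u -= coal
                    acc = 0.0
                    d = -1
                    for dd in range(npop):
                        if counts[dd] and row_sum[dd] > 0:
                            d = dd
                            acc += counts[dd] * row_sum[dd]
                            if u < acc:
                                break
                    i = _pick_in_deme(deme_of, counts[d], d, rng)
                    v = unif() * row_sum[d]
                    acc2 = 0.0
                    dst = d
                    for dd in range(npop):
                        if mig[d, dd] > 0:
                            dst = dd
                            acc2 += mig[d, dd]
                            if v < acc2:
                                break
                    deme_of[i] = dst
                    counts[d] -= 1
                    counts[dst] += 1
        # apply all events scheduled at time t
        while ei < len(events) and events[ei][0] <= t:
            _, kind, src, dst, frac, size, matrix = events[ei]
            ei += 1
            if kind == "split":
                for i in range(len(deme_of)):
                    if deme_of[i] == src:
                        deme_of[i] = dst
                counts[dst] += counts[src]
                counts[src] = 0
                mig[src, :] = 0.0
                mig[:, src] = 0.0
                row_sum = mig.sum(axis=1)
            elif kind == "admixture_pulse":
                if frac >= 1.0:
                    for i in range(len(deme_of)):
                        if deme_of[i] == src:
                            deme_of[i] = dst
                    counts[dst] += counts[src]
                    counts[src] = 0
                else:
                    for i in range(len(deme_of)):
                        if deme_of[i] == src and unif() < frac:
                            deme_of[i] = dst
                            counts[src] -= 1
                            counts[dst] += 1
            elif kind == "size_change":
                sizes[src] = size
            elif kind == "migration_change":
                mig = matrix.copy()
                row_sum = mig.sum(axis=1)
    return branches


def _pick_in_deme(deme_of: list[int], k: int, d: int, rng: random.Random) -> int:
    j = rng.randrange(k)
    seen = -1
    for i, dd in enumerate(deme_of):
        if dd == d:
            seen += 1
            if seen == j:
                return i
    raise AssertionError("deme count out of sync")


def _pick_pair(deme_of: list[int], k: int, d: int, rng: random.Random):
    j1 = rng.randrange(k)
    j2 = rng.randrange(k - 1)
    if j2 >= j1:
        j2 += 1
    i1 = i2 = -1
    seen = -1
    for i, dd in enumerate(deme_of):
        if dd == d:
            seen += 1
            if seen == j1:
                i1 = i
            if seen == j2:
                i2 = i
            if i1 >= 0 and i2 >= 0:
                return i1, i2
    raise AssertionError("deme count out of sync")


def _iter_trees(
    demog: Demography, n_trees: int, seed: int, max_steps: int
) -> Iterator[list]:
    prep = _prepare(demog)
    for locus in range(n_trees):
        yield simulate_branches(
            demog, locus_rng(seed, locus), max_steps=max_steps, _prep=prep
        )


def _small_poisson(lam: float, rng: random.Random) -> int:
    """Knuth's method; adequate for the per-locus regime (lam well below ~30)."""
    if lam <= 0.0:
        return 0
    limit = math.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def simulate_sfs(
    demog: Demography,
    n_loci: int,
    seed: int,
    folded: bool = False,
    max_steps: int = 1_000_000,
) -> SFS:
    """Joint SFS of ``n_loci`` independent sites under Poisson mutation.

    Each locus gets Poisson(mu * total branch length) mutations placed on
    branches proportionally to length.  With realistic mutation rates most
    loci are monomorphic and contribute nothing; use ``simulate_snp_sfs``
    to generate a spectrum with a fixed number of segregating sites.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    _require_samples(demog)
    shape = sfs_shape(demog)
    counts = np.zeros(shape)
    mu = demog.mu
    prep = _prepare(demog)
    for locus in range(n_loci):
        rng = locus_rng(seed, locus)
        branches = simulate_branches(demog, rng, max_steps=max_steps, _prep=prep)
        total = sum(b[1] for b in branches)
        nmut = _small_poisson(mu * total, rng)
        for _ in range(nmut):
            u = rng.random() * total
            acc = 0.0
            for cfg, length in branches:
                acc += length
                if u < acc:
                    counts[cfg] += 1
                    break
    out = SFS(labels=demog.sampled_labels, counts=counts, folded=False)
    return out.fold() if folded else out


def _pooled_lengths(demog, n_trees, seed, max_steps):
    shape = sfs_shape(demog)
    lengths = np.zeros(shape)
    for branches in _iter_trees(demog, n_trees, seed, max_steps):
        for cfg, length in branches:
            lengths[cfg] += length
    return lengths


def simulate_snp_sfs(
    demog: Demography,
    n_snps: int,
    n_trees: int,
    seed: int,
    folded: bool = False,
    max_steps: int = 1_000_000,
) -> SFS:
    """Joint SFS with exactly ``n_snps`` segregating sites.

    Pools branch lengths over ``n_trees`` independent genealogies and
    distributes the sites multinomially over cells in proportion to pooled
    length (the small-mu limit of Poisson mutation conditioned on the total
    number of segregating sites).
    """
    if n_snps < 1 or n_trees < 1:
        raise ValueError("n_snps and n_trees must be >= 1")
    _require_samples(demog)
    lengths = _pooled_lengths(demog, n_trees, seed, max_steps)
    total = lengths.sum()
    if total <= 0:
        raise CoalescenceError("no branch length accumulated")
    gen = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(_MULTINOMIAL_KEY,)))
    )
    flat = gen.multinomial(n_snps, (lengths / total).ravel())
    out = SFS(
        labels=demog.sampled_labels,
        counts=flat.reshape(lengths.shape).astype(float),
        folded=False,
    )
    return out.fold() if folded else out


def expected_sfs_probs(
    demog: Demography,
    n_sims: int,
    seed: int,
    p_min: float | None = None,
    folded: bool = False,
    max_steps: int = 1_000_000,
) -> np.ndarray:
    """Per-SNP probability of each joint-SFS cell, by Monte Carlo.

    Estimated as pooled branch length per cell over ``n_sims`` genealogies,
    normalized over polymorphic cells.  With ``p_min`` set, zero cells are
    floored at ``p_min`` and the vector renormalized (the composite
    likelihood applies its own floor, so the default leaves zeros alone).
    Monomorphic corner cells (derived count 0 or maximal in every
    population at once) carry no mass by construction.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable expectation")
    _require_samples(demog)
    lengths = _pooled_lengths(demog, n_sims, seed, max_steps)
    allowed = np.ones_like(lengths, dtype=bool)
    if folded:
        labels = demog.sampled_labels
        lengths = SFS(labels, lengths, folded=False).fold().counts
        # cells folded away are structural zeros and must stay zero
        allowed = SFS(labels, np.ones_like(lengths), folded=False).fold().counts > 0
    total = lengths.sum()
    if total <= 0:
        raise CoalescenceError("no branch length accumulated")
    probs = lengths / total
    if p_min is not None:
        probs = np.where(allowed, np.maximum(probs, p_min), 0.0)
        probs /= probs.sum()
    return probs


def _require_samples(demog: Demography) -> None:
    if not demog.sampled_labels:
        raise ValueError("demography has no sampled demes (all n_samples == 0)")
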