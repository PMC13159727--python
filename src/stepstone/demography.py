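"""Demographic models as backward-time event programs over labelled demes.

A :class:`Demography` is a set of demes (each with a diploid effective size
and a number of sampled diploids) plus an ordered list of backward-time
events: population splits, admixture pulses, migration-matrix changes and
size changes.  Looking backward in time, a *split* moves every lineage of
the source deme into the destination deme (the forward-time founding of the
source from the destination), while an *admixture pulse* moves each source
lineage independently with probability ``fraction`` (the forward-time
admixture proportion contributed by the destination).

All times are in generations before present.  Helpers convert from years
and ka (thousand years) using the demography's generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DemeConfig",
    "DemographicEvent",
    "Demography",
    "Param",
    "ParamSpace",
    "DemographyError",
    "split",
    "admixture_pulse",
    "size_change",
    "migration_change",
]

EVENT_KINDS = ("split", "admixture_pulse", "migration_change", "size_change")


class DemographyError(ValueError):
    """A demography violates one of its structural invariants."""


@dataclass(frozen=True)
class DemeConfig:
    """One deme: a label, a diploid effective size and a diploid sample size."""

    label: str
    Ne: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise DemographyError("deme label must be non-empty")
        if not np.isfinite(self.Ne) or self.Ne <= 0:
            raise DemographyError(f"deme {self.label!r}: Ne must be > 0, got {self.Ne}")
        if self.n_samples < 0:
            raise DemographyError(f"deme {self.label!r}: n_samples must be >= 0")


@dataclass(frozen=True)
class DemographicEvent:
    """A single backward-time event.

    ``split``            : all lineages of ``source`` move into ``dest``.
    ``admixture_pulse``  : each lineage of ``source`` moves into ``dest``
                           independently with probability ``fraction``.
    ``size_change``      : ``source`` deme's Ne becomes ``size``.
    ``migration_change`` : the backward migration matrix becomes ``matrix``.
    """

    time: float
    kind: str
    source: str | None = None
    dest: str | None = None
    fraction: float | None = None
    size: float | None = None
    matrix: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.time < 0 or not np.isfinite(self.time):
            raise DemographyError(f"event time must be finite and >= 0, got {self.time}")
        if self.kind not in EVENT_KINDS:
            raise DemographyError(f"unknown event kind {self.kind!r}")
        if self.kind in ("split", "admixture_pulse"):
            if self.source is None or self.dest is None:
                raise DemographyError(f"{self.kind} requires source and dest")
            if self.source == self.dest:
                raise DemographyError(f"{self.kind}: source and dest must differ")
        if self.kind == "admixture_pulse":
            if self.fraction is None or not (0.0 <= self.fraction <= 1.0):
                raise DemographyError(
                    f"admixture fraction must lie in [0, 1], got {self.fraction}"
                )
        if self.kind == "size_change":
            if self.source is None or self.size is None or self.size <= 0:
                raise DemographyError("size_change requires a source deme and size > 0")
        if self.kind == "migration_change" and self.matrix is None:
            raise DemographyError("migration_change requires a matrix")


def split(time: float, source: str, dest: str) -> DemographicEvent:
    return DemographicEvent(time=time, kind="split", source=source, dest=dest)


def admixture_pulse(time: float, source: str, dest: str, fraction: float) -> DemographicEvent:
    return DemographicEvent(
        time=time, kind="admixture_pulse", source=source, dest=dest, fraction=fraction
    )


def size_change(time: float, deme: str, size: float) -> DemographicEvent:
    return DemographicEvent(time=time, kind="size_change", source=deme, size=size)


def migration_change(time: float, matrix: np.ndarray) -> DemographicEvent:
    m = tuple(tuple(float(x) for x in row) for row in np.asarray(matrix, dtype=float))
    return DemographicEvent(time=time, kind="migration_change", matrix=m)


@dataclass(frozen=True)
class Demography:
    """Demes + ordered backward-time events + migration + mutation parameters.

    ``migration0[i][j]`` is the per-generation backward rate at which a
    lineage currently in deme ``i`` moves to deme ``j``.  ``mu`` is the
    per-site per-generation mutation rate; ``gen_time_years`` converts
    generations to calendar time for I/O only.
    """

    demes: tuple[DemeConfig, ...]
    events: tuple[DemographicEvent, ...] = ()
    migration0: tuple[tuple[float, ...], ...] | None = None
    mu: float = 1.36e-8
    gen_time_years: float = 10.0

    def __post_init__(self) -> None:
        demes = tuple(self.demes)
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "demes", demes)
        object.__setattr__(self, "events", events)
        labels = [d.label for d in demes]
        if len(set(labels)) != len(labels):
            raise DemographyError(f"deme labels must be unique, got {labels}")
        if self.mu < 0:
            raise DemographyError(f"mu must be >= 0, got {self.mu}")
        if self.gen_time_years <= 0:
            raise DemographyError("gen_time_years must be > 0")
        k = len(demes)
        if self.migration0 is None:
            object.__setattr__(
                self, "migration0", tuple(tuple(0.0 for _ in range(k)) for _ in range(k))
            )
        m = np.asarray(self.migration0, dtype=float)
        if m.shape != (k, k):
            raise DemographyError(f"migration matrix must be {k}x{k}, got {m.shape}")
        if (m < 0).any() or not np.isfinite(m).all():
            raise DemographyError("migration rates must be finite and >= 0")
        object.__setattr__(
            self, "migration0", tuple(tuple(float(x) for x in row) for row in m)
        )
        idx = self.index
        for ev in events:
            for lab in (ev.source, ev.dest):
                if lab is not None and lab not in idx:
                    raise DemographyError(f"event references unknown deme {lab!r}")
            if ev.matrix is not None and np.asarray(ev.matrix).shape != (k, k):
                raise DemographyError("migration_change matrix has wrong shape")
        self._check_single_ancestor()

    # -- structural queries -------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.demes)

    @property
    def index(self) -> dict[str, int]:
        return {d.label: i for i, d in enumerate(self.demes)}

    @property
    def sampled_labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.demes if d.n_samples > 0)

    def haploid_sample_sizes(self) -> dict[str, int]:
        return {d.label: 2 * d.n_samples for d in self.demes if d.n_samples > 0}

    def _check_single_ancestor(self) -> None:
        """Trace events backward: all sampled lineages must end up able to
        coalesce in a single ancestral deme (directly, or through migration
        in the final epoch)."""
        active = {d.label for d in self.demes if d.n_samples > 0}
        if not active:
            active = {d.label for d in self.demes}
        final_m = np.asarray(self.migration0, dtype=float)
        for ev in self.events:
            if ev.kind == "split" and ev.source in active:
                active.discard(ev.source)
                active.add(ev.dest)
            elif ev.kind == "admixture_pulse" and ev.source in active:
                active.add(ev.dest)
                if ev.fraction is not None and ev.fraction >= 1.0:
                    active.discard(ev.source)
            elif ev.kind == "migration_change":
                final_m = np.asarray(ev.matrix, dtype=float)
        if len(active) == 1:
            return
        # >1 terminal deme is fine only if the final migration matrix
        # connects them (lineages can still find one another).
        idx = self.index
        sub = [idx[a] for a in sorted(active)]
        adj = (final_m[np.ix_(sub, sub)] > 0) | (final_m[np.ix_(sub, sub)].T > 0)
        if not _connected(adj):
            raise DemographyError(
                "event program leaves more than one isolated ancestral deme: "
                + ", ".join(sorted(active))
            )

    # -- conversions --------------------------------------------------------

    def generations_from_years(self, years: float) -> float:
        return years / self.gen_time_years

    def generations_from_ka(self, ka: float) -> float:
        return 1000.0 * ka / self.gen_time_years

    def ka_from_generations(self, generations: float) -> float:
        return generations * self.gen_time_years / 1000.0

    def with_samples(self, samples: Mapping[str, int]) -> "Demography":
        """Return a copy with per-deme diploid sample sizes replaced."""
        idx = self.index
        for lab in samples:
            if lab not in idx:
                raise DemographyError(f"unknown deme {lab!r} in samples")
        demes = tuple(
            replace(d, n_samples=int(samples.get(d.label, 0))) for d in self.demes
        )
        return replace(self, demes=demes)


def _connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    if n <= 1:
        return True
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return len(seen) == n


# ---------------------------------------------------------------------------
# Parameter spaces


@dataclass(frozen=True)
class Param:
    """One free parameter: bounds and search scale ('linear' or 'log')."""

    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DemographyError(f"parameter bounds require lower < upper, got {self}")
        if self.scale not in ("linear", "log"):
            raise DemographyError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.lower <= 0:
            raise DemographyError("log-scale parameter requires lower > 0")

    def transform(self, value: float) -> float:
        return float(np.log(value)) if self.scale == "log" else float(value)

    def untransform(self, x: float) -> float:
        return float(np.exp(x)) if self.scale == "log" else float(x)

    @property
    def bounds_transformed(self) -> tuple[float, float]:
        return self.transform(self.lower), self.transform(self.upper)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


class ParamSpace(dict):
    """Named free parameters, each appearing exactly once, with bounds.

    A thin ``dict[str, Param]`` with validation helpers; insertion order is
    the default conditional-maximization order.
    """

    def __init__(self, params: Mapping[str, Param]):
        super().__init__(params)

    def validate(self, values: Mapping[str, float]) -> None:
        for name, p in self.items():
            if name not in values:
                raise KeyError(f"missing parameter {name!r}")
            if not p.contains(values[name]):
                raise DemographyError(
                    f"parameter {name}={values[name]} outside bounds "
                    f"[{p.lower}, {p.upper}]"
                )

    def names(self) -> list[str]:
        return list(self)
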