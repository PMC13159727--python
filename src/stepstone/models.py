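"""Named demographic models for a five-population stepping-stone system.

The between-cluster models describe five populations (labelled SW, SE, C,
NC, N) arranged along a south-to-north geographic axis, with SE lying
between SW and C and NC lying between C and N.  Two origin hypotheses
(southwestern vs central root) and six dispersal scenarios are provided:

``origin_SW``          serial founding from a southwestern root
``origin_C``           serial founding from a central root
``model1_stepping``    pure stepping-stone: SE buds off SW, NC off N,
                       N off C, C off SW; no admixture, no migration
``model2_SE_admix``    stepping-stone + admixed origin of SE
``model3_NC_admix``    stepping-stone + admixed origin of NC
``model4_SE_NC_admix`` stepping-stone + admixed origins of both SE and NC
``model5_IM``          stepping-stone topology + continuous symmetric
                       migration between geographic neighbours
``model6_independent`` all populations split independently from the root
                       lineage, migration between all pairs

An admixed origin at time T is compiled, backward in time, as an admixture
pulse moving fraction ``alpha`` of the daughter's lineages into the minor
parent followed by a same-time split of the remainder into the major
parent.  With ``alpha = 1.0`` the split is vacuous and model4 degenerates
exactly to model1 (a pulse of fraction one is a split).

Within-cluster models (``within_SW``, ``within_C``, ``within_NC``,
``within_N``) are small isolation-with-migration programs over the 2-3
subpopulations each cluster resolves into.

Backward-time parameter conventions: ``T1 > T2 > T3 > T4`` are event times
in generations (T1 the deepest split); ``N_x`` are diploid effective sizes;
``alpha_SE``/``alpha_NC`` are admixture fractions; ``m`` a per-generation
backward migration rate.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .demography import (
    Demography,
    DemeConfig,
    DemographyError,
    Param,
    ParamSpace,
    admixture_pulse,
    split,
)

__all__ = [
    "MODEL_NAMES",
    "CLUSTERS",
    "build_named_model",
    "param_space",
    "required_params",
    "time_order",
    "BEST_FIT_SE_NC_ADMIX",
]

CLUSTERS = ("SW", "SE", "C", "NC", "N")

# Geographic neighbour pairs along the south-to-north axis.
_ADJACENT = (("SW", "SE"), ("SE", "C"), ("C", "NC"), ("NC", "N"))

_BETWEEN = (
    "origin_SW",
    "origin_C",
    "model1_stepping",
    "model2_SE_admix",
    "model3_NC_admix",
    "model4_SE_NC_admix",
    "model5_IM",
    "model6_independent",
)
_WITHIN = ("within_SW", "within_C", "within_NC", "within_N")
MODEL_NAMES = _BETWEEN + _WITHIN

# Subpopulation counts per cluster (from the study system's PCA structure).
_WITHIN_DEMES = {"within_SW": 3, "within_C": 2, "within_NC": 3, "within_N": 2}

# Point estimates for the five-population system used as the default
# synthetic-truth scenario: SW-C divergence ~128.5 ka, C-N ~106.3 ka,
# admixed origin of NC ~13.5 ka (81% N + 19% C) and of SE ~8.2 ka
# (37% SW + 63% C), in generations at 10 years/generation.  Effective
# sizes are not part of the published point estimate; 2000 diploids per
# deme is the package's documented scenario choice.
BEST_FIT_SE_NC_ADMIX: dict[str, float] = {
    "T1": 12850.0,
    "T2": 10630.0,
    "T3": 1350.0,
    "T4": 820.0,
    "alpha_SE": 0.37,
    "alpha_NC": 0.81,
    "N_SW": 2000.0,
    "N_SE": 2000.0,
    "N_C": 2000.0,
    "N_NC": 2000.0,
    "N_N": 2000.0,
}

_NE = Param(50.0, 1e4)
_T = Param(100.0, 5e4)
_T_WITHIN = Param(10.0, 5e4)  # within-cluster divergences are very recent
_M = Param(1e-6, 1e-2, scale="log")
_ALPHA = Param(0.0, 1.0)


def _between_space(alphas: tuple[str, ...] = (), migration: bool = False) -> ParamSpace:
    params: dict[str, Param] = {f"T{i}": _T for i in (1, 2, 3, 4)}
    params.update({f"N_{lab}": _NE for lab in CLUSTERS})
    for a in alphas:
        params[a] = _ALPHA
    if migration:
        params["m"] = _M
    return ParamSpace(params)


def param_space(name: str) -> ParamSpace:
    """Free parameters (bounds and scales) of a named model."""
    if name in ("origin_SW", "origin_C", "model5_IM", "model6_independent"):
        return _between_space(migration=True)
    if name == "model1_stepping":
        return _between_space()
    if name == "model2_SE_admix":
        return _between_space(alphas=("alpha_SE",))
    if name == "model3_NC_admix":
        return _between_space(alphas=("alpha_NC",))
    if name == "model4_SE_NC_admix":
        return _between_space(alphas=("alpha_SE", "alpha_NC"))
    if name in _WITHIN:
        k = _WITHIN_DEMES[name]
        params: dict[str, Param] = {f"T{i}": _T_WITHIN for i in range(1, k)}
        params.update({f"N_{i}": _NE for i in range(1, k + 1)})
        params["m"] = _M
        return ParamSpace(params)
    raise KeyError(f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}")


def required_params(name: str) -> list[str]:
    return param_space(name).names()


def time_order(name: str) -> list[str]:
    """Time parameters oldest-to-youngest (their ordering constraint)."""
    if name in _BETWEEN:
        return ["T1", "T2", "T3", "T4"]
    k = _WITHIN_DEMES[name]
    return [f"T{i}" for i in range(1, k)]


def _check_time_order(name: str, params: Mapping[str, float]) -> None:
    order = time_order(name)
    for older, younger in zip(order, order[1:]):
        if not params[older] > params[younger]:
            raise DemographyError(
                f"{name}: event-time ordering violated: require "
                + " > ".join(order)
                + f" (got {older}={params[older]}, {younger}={params[younger]})"
            )


def build_named_model(
    name: str,
    params: Mapping[str, float],
    samples: Mapping[str, int] | None = None,
    mu: float = 1.36e-8,
    gen_time_years: float = 10.0,
) -> Demography:
    """Compile a named model with concrete parameter values to a Demography.

    ``samples`` maps deme labels to diploid sample counts (default 0; set
    them before simulating).  Raises ``KeyError`` for an unknown model or a
    missing parameter and ``DemographyError`` for out-of-bounds values or
    an event-time ordering violation.
    """
    space = param_space(name)
    missing = [p for p in space if p not in params]
    if missing:
        raise KeyError(f"{name}: missing parameter(s) {', '.join(missing)}")
    unknown = [p for p in params if p not in space]
    if unknown:
        raise KeyError(f"{name}: unknown parameter(s) {', '.join(unknown)}")
    space.validate(params)
    _check_time_order(name, params)

    if name in _BETWEEN:
        demog = _build_between(name, dict(params), mu, gen_time_years)
    else:
        demog = _build_within(name, dict(params), mu, gen_time_years)
    if samples:
        demog = demog.with_samples(samples)
    return demog


def _adjacency_migration(rate: float, pairs=_ADJACENT) -> np.ndarray:
    m = np.zeros((len(CLUSTERS), len(CLUSTERS)))
    idx = {lab: i for i, lab in enumerate(CLUSTERS)}
    for a, b in pairs:
        m[idx[a], idx[b]] = rate
        m[idx[b], idx[a]] = rate
    return m


def _build_between(name: str, p: dict, mu: float, gen_time: float) -> Demography:
    demes = tuple(DemeConfig(lab, p[f"N_{lab}"]) for lab in CLUSTERS)
    T1, T2, T3, T4 = p["T1"], p["T2"], p["T3"], p["T4"]
    events: list = []
    migration = None

    if name in ("model1_stepping", "model2_SE_admix", "model3_NC_admix",
                "model4_SE_NC_admix", "model5_IM"):
        # Admixed origins: pulse into the minor parent, remainder into the
        # major parent; without the pulse the daughter merges wholly into
        # its single parent (SE into SW, NC into N).
        if name in ("model2_SE_admix", "model4_SE_NC_admix"):
            events.append(admixture_pulse(T4, "SE", "SW", p["alpha_SE"]))
            events.append(split(T4, "SE", "C"))
        else:
            events.append(split(T4, "SE", "SW"))
        if name in ("model3_NC_admix", "model4_SE_NC_admix"):
            events.append(admixture_pulse(T3, "NC", "N", p["alpha_NC"]))
            events.append(split(T3, "NC", "C"))
        else:
            events.append(split(T3, "NC", "N"))
        events.append(split(T2, "N", "C"))
        events.append(split(T1, "C", "SW"))
        if name == "model5_IM":
            migration = _adjacency_migration(p["m"])
    elif name == "model6_independent":
        events += [split(T4, "SE", "SW"), split(T3, "NC", "SW"),
                   split(T2, "N", "SW"), split(T1, "C", "SW")]
        migration = np.full((5, 5), p["m"])
        np.fill_diagonal(migration, 0.0)
    elif name == "origin_SW":
        events += [split(T4, "SE", "SW"), split(T3, "NC", "C"),
                   split(T2, "N", "C"), split(T1, "C", "SW")]
        migration = _adjacency_migration(p["m"])
    elif name == "origin_C":
        events += [split(T4, "SE", "C"), split(T3, "NC", "C"),
                   split(T2, "N", "C"), split(T1, "SW", "C")]
        migration = _adjacency_migration(p["m"])
    else:  # pragma: no cover
        raise KeyError(name)

    return Demography(
        demes=demes,
        events=tuple(events),
        migration0=None if migration is None else tuple(map(tuple, migration)),
        mu=mu,
        gen_time_years=gen_time,
    )


def _build_within(name: str, p: dict, mu: float, gen_time: float) -> Demography:
    cluster = name.split("_", 1)[1]
    k = _WITHIN_DEMES[name]
    labels = [f"{cluster}{i}" for i in range(1, k + 1)]
    demes = tuple(DemeConfig(lab, p[f"N_{i + 1}"]) for i, lab in enumerate(labels))
    # Serial splits: the youngest subpopulation buds off its neighbour.
    events = [split(p[f"T{i}"], labels[i], labels[i - 1]) for i in range(1, k)]
    m = np.full((k, k), p["m"])
    np.fill_diagonal(m, 0.0)
    return Demography(
        demes=demes,
        events=tuple(events),
        migration0=tuple(map(tuple, m)),
        mu=mu,
        gen_time_years=gen_time,
    )
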