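"""Simulation-based composite-likelihood fitting of demographic models.

The objective is the multinomial composite log-likelihood of an observed
joint SFS against Monte-Carlo expected cell probabilities:

    lnCL = sum_i m_i * ln(max(p_i, p_min))

over polymorphic cells, where m_i are observed counts and p_i the expected
per-SNP probabilities estimated by coalescent simulation.  Cells the
simulation never visited are floored at ``p_min`` (default 1/(10 n_sims)).

Fitting runs expectation-conditional-maximization (ECM) cycles: one
bounded Brent line search per free parameter per cycle, with common random
numbers shared by all probes within a cycle so the line search sees a
smooth objective.  Models are ranked by AIC = 2k - 2 lnCL (natural-log
convention; use ``aic_from_log10`` for likelihoods reported in log10).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import models as _models
from .coalescent import expected_sfs_probs, simulate_snp_sfs
from .demography import DemographyError, ParamSpace
from .sfs import SFS, polymorphic_mask

__all__ = [
    "FitResult",
    "BootstrapCI",
    "composite_log_likelihood",
    "fit_model_ecm",
    "compare_models",
    "profile_likelihood",
    "parametric_bootstrap_ci",
    "aic_from_log10",
]

_BAD = -1e18


def default_p_min(n_sims: int) -> float:
    return 1.0 / (10.0 * n_sims)


def aic_from_log10(k: int, log10_likelihood: float) -> float:
    """AIC from a log10 composite likelihood (fastsimcoal convention)."""
    return 2.0 * k - 2.0 * np.log(10.0) * log10_likelihood


def obs_digest(obs: SFS) -> str:
    h = hashlib.sha256()
    h.update(repr(obs.labels).encode())
    h.update(np.ascontiguousarray(obs.counts).tobytes())
    h.update(b"folded" if obs.folded else b"unfolded")
    return h.hexdigest()[:16]


def composite_log_likelihood(
    obs: SFS, probs: np.ndarray, p_min: float
) -> float:
    """Multinomial composite log-likelihood over polymorphic SFS cells."""
    if p_min <= 0:
        raise ValueError("p_min must be > 0")
    probs = np.asarray(probs, dtype=float)
    if probs.shape != obs.counts.shape:
        raise ValueError(
            f"obs shape {obs.counts.shape} != probs shape {probs.shape}"
        )
    mask = polymorphic_mask(obs.counts.shape)
    m = obs.counts[mask]
    p = np.maximum(probs[mask], p_min)
    return float((m * np.log(p)).sum())


@dataclass
class FitResult:
    """Outcome of one composite-likelihood fit."""

    model: str
    params: dict[str, float]
    lnCL: float
    k: int
    n_sims: int
    trace: list[float] = field(default_factory=list)
    seed: int = 0
    converged: bool = False
    obs_hash: str = ""

    @property
    def AIC(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnCL

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "lnCL": float(self.lnCL),
            "k": self.k,
            "AIC": float(self.AIC),
            "n_sims": self.n_sims,
            "trace": [float(x) for x in self.trace],
            "seed": self.seed,
            "converged": self.converged,
            "obs_hash": self.obs_hash,
        }


@dataclass
class BootstrapCI:
    level: float
    lower: dict[str, float]
    upper: dict[str, float]
    n_boot: int
    seed: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "lower": dict(self.lower),
            "upper": dict(self.upper),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def _samples_from_obs(model: str, obs: SFS) -> dict[str, int]:
    """Diploid sample sizes per deme implied by the observed SFS axes."""
    samples = {}
    for lab, nh in zip(obs.labels, obs.n_haploid):
        if nh % 2:
            raise ValueError(
                f"axis {lab} has odd haploid size {nh}; diploid samples required"
            )
        samples[lab] = nh // 2
    return samples


def _objective_factory(
    model: str,
    obs: SFS,
    fixed: Mapping[str, float],
    n_sims: int,
    p_min: float | None,
    samples: Mapping[str, int],
):
    pm = p_min if p_min is not None else default_p_min(n_sims)

    def objective(values: Mapping[str, float], seed: int) -> float:
        params = {**fixed, **values}
        try:
            demog = _models.build_named_model(model, params, samples=samples)
        except (DemographyError, KeyError):
            return _BAD
        probs = expected_sfs_probs(demog, n_sims=n_sims, seed=seed, folded=obs.folded)
        return composite_log_likelihood(obs, probs, pm)

    return objective


def _ecm_order(space: ParamSpace, free: Sequence[str]) -> list[str]:
    """Times oldest to youngest, then sizes, then admixture fractions,
    then migration rates."""
    def rank(name: str):
        if name.startswith("T"):
            return (0, name)
        if name.startswith("N"):
            return (1, name)
        if name.startswith("alpha"):
            return (2, name)
        return (3, name)

    return sorted(free, key=rank)


def fit_model_ecm(
    model: str,
    obs: SFS,
    n_sims: int = 5000,
    cycles: int = 40,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
    start: Mapping[str, float] | None = None,
    p_min: float | None = None,
    param_order: Sequence[str] | None = None,
    line_search_iters: int = 8,
    crn_across_cycles: bool = False,
) -> FitResult:
    """Fit a named model to an observed SFS by ECM composite likelihood.

    ``fixed`` pins parameters (not counted in k); the rest are free and
    optimized one at a time per cycle with a bounded Brent search, under
    common random numbers within each cycle (and across cycles if
    ``crn_across_cycles``).  Start values default to the bound midpoint
    (geometric midpoint for log-scale parameters).  Deterministic given
    ``seed``.
    """
    space = _models.param_space(model)
    fixed = dict(fixed or {})
    free = [p for p in space if p not in fixed]
    if not free:
        raise ValueError("no free parameters to fit")
    samples = _samples_from_obs(model, obs)
    objective = _objective_factory(model, obs, fixed, n_sims, p_min, samples)
    order = list(param_order) if param_order else _ecm_order(space, free)
    torder = _models.time_order(model)

    current: dict[str, float] = {}
    for name in free:
        p = space[name]
        if start and name in start:
            current[name] = float(start[name])
        elif p.scale == "log":
            current[name] = float(np.sqrt(p.lower * p.upper))
        else:
            current[name] = 0.5 * (p.lower + p.upper)
    # make the start obey the time-ordering constraint
    prev = None
    for t in torder:
        if t in current and prev is not None and current[t] >= prev:
            current[t] = 0.5 * prev
        prev = fixed.get(t, current.get(t))

    ss = np.random.SeedSequence(seed)
    cycle_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(cycles)]
    if crn_across_cycles:
        cycle_seeds = [cycle_seeds[0]] * cycles

    best = _BAD
    trace: list[float] = []
    aborted = False
    for c in range(cycles):
        cseed = cycle_seeds[c]
        cur_ln = objective(current, cseed)
        if cur_ln <= _BAD:
            aborted = True
            break
        for name in order:
            p = space[name]
            lo_b, hi_b = p.lower, p.upper
            if name in torder:
                i = torder.index(name)
                if i > 0:
                    older = torder[i - 1]
                    hi_b = min(hi_b, (fixed.get(older) or current[older]) * 0.999)
                if i + 1 < len(torder):
                    younger = torder[i + 1]
                    lo_b = max(lo_b, (fixed.get(younger) or current[younger]) * 1.001)
                if lo_b >= hi_b:
                    continue
            tlo, thi = p.transform(lo_b), p.transform(hi_b)

            def f(x: float, _name=name) -> float:
                trial = dict(current)
                trial[_name] = p.untransform(x)
                return -objective(trial, cseed)

            res = minimize_scalar(
                f,
                bounds=(tlo, thi),
                method="bounded",
                options={"maxiter": line_search_iters, "xatol": (thi - tlo) * 1e-3},
            )
            if -res.fun >= cur_ln:
                current[name] = p.untransform(float(res.x))
                cur_ln = -float(res.fun)
        trace.append(cur_ln)
        best = cur_ln
    if aborted and not trace:
        raise RuntimeError(
            f"{model}: composite likelihood non-finite at every probe; "
            "check the observed SFS and parameter space"
        )
    converged = len(trace) == cycles and (
        len(trace) < 2 or abs(trace[-1] - trace[-2]) < max(1.0, 1e-4 * abs(trace[-1]))
    )
    return FitResult(
        model=model,
        params={**{k: float(v) for k, v in current.items()}, **{k: float(v) for k, v in fixed.items()}},
        lnCL=float(best),
        k=len(free),
        n_sims=n_sims,
        trace=trace,
        seed=seed,
        converged=converged,
        obs_hash=obs_digest(obs),
    )


def fit_with_restarts(
    model: str,
    obs: SFS,
    n_restarts: int,
    seed: int,
    **kwargs,
) -> list[FitResult]:
    """Independent ECM runs with distinct seeds (local-optimum insurance)."""
    seeds = [
        int(s.generate_state(1)[0] >> 1)
        for s in np.random.SeedSequence(seed).spawn(n_restarts)
    ]
    return [fit_model_ecm(model, obs, seed=s, **kwargs) for s in seeds]


def compare_models(fits: Sequence[FitResult]) -> list[dict]:
    """Rank fits by AIC (ascending), taking the best restart per model.

    All fits must be on the same observed SFS.  Returns one row per model
    with AIC, delta-AIC from the best, lnCL and the fitted parameters.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    hashes = {f.obs_hash for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits were computed on different observed data")
    best_per_model: dict[str, FitResult] = {}
    for f in fits:
        cur = best_per_model.get(f.model)
        if cur is None or f.lnCL > cur.lnCL:
            best_per_model[f.model] = f
    rows = sorted(best_per_model.values(), key=lambda f: f.AIC)
    a0 = rows[0].AIC
    return [
        {
            "model": f.model,
            "AIC": float(f.AIC),
            "delta_AIC": float(f.AIC - a0),
            "lnCL": float(f.lnCL),
            "k": f.k,
            "params": {k: float(v) for k, v in f.params.items()},
        }
        for f in rows
    ]


def profile_likelihood(
    model: str,
    obs: SFS,
    focal: str,
    grid: Sequence[float],
    fixed: Mapping[str, float],
    n_sims: int = 2000,
    seed: int = 0,
    p_min: float | None = None,
) -> dict:
    """Composite log-likelihood along a grid of one parameter.

    All other parameters are held at ``fixed``; every grid point is
    evaluated with the same seed (common random numbers), so differences
    along the grid reflect the parameter, not Monte-Carlo noise.  Grid
    points violating the model's constraints score -inf.  Returns
    ``{"grid", "lnCL", "argmax"}``.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty profile grid")
    others = {k: v for k, v in fixed.items() if k != focal}
    samples = _samples_from_obs(model, obs)
    objective = _objective_factory(model, obs, others, n_sims, p_min, samples)
    lnCL = np.array([objective({focal: g}, seed) for g in grid])
    finite = lnCL > _BAD
    if not finite.any():
        raise RuntimeError("profile likelihood non-finite on the whole grid")
    masked = np.where(finite, lnCL, -np.inf)
    return {
        "grid": np.asarray(grid),
        "lnCL": masked,
        "argmax": float(grid[int(masked.argmax())]),
    }


def parametric_bootstrap_ci(
    fit: FitResult,
    obs: SFS,
    n_boot: int,
    level: float = 0.95,
    seed: int = 0,
    refit_free: Sequence[str] | None = None,
    n_sims: int = 1000,
    n_trees: int = 1000,
    cycles: int = 1,
    max_failure_rate: float = 0.2,
) -> BootstrapCI:
    """Percentile bootstrap intervals by simulate-at-estimate, refit-each.

    Each replicate simulates an SFS with the same number of segregating
    sites as ``obs`` from the fitted parameters, then refits with reduced
    settings (``refit_free`` defaults to all free parameters of the fit).
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap an unconverged fit")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    samples = _samples_from_obs(fit.model, obs)
    free = list(refit_free) if refit_free else [
        p for p in _models.param_space(fit.model) if p in fit.params
    ]
    fixed = {k: v for k, v in fit.params.items() if k not in free}
    n_snps = int(round(obs.total()))
    ss = np.random.SeedSequence(seed)
    reps: dict[str, list[float]] = {p: [] for p in free}
    n_failed = 0
    for b, child in enumerate(ss.spawn(n_boot)):
        bseed = int(child.generate_state(1)[0] >> 1)
        demog = _models.build_named_model(fit.model, fit.params, samples=samples)
        boot_obs = simulate_snp_sfs(demog, n_snps, n_trees, seed=bseed, folded=obs.folded)
        try:
            refit = fit_model_ecm(
                fit.model,
                boot_obs,
                n_sims=n_sims,
                cycles=cycles,
                seed=bseed,
                fixed=fixed,
                start={p: fit.params[p] for p in free},
            )
        except RuntimeError:
            n_failed += 1
            continue
        for p in free:
            reps[p].append(refit.params[p])
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {n_failed}/{n_boot} exceeds "
            f"{max_failure_rate:.0%}"
        )
    alpha = (1.0 - level) / 2.0
    lower = {p: float(np.quantile(reps[p], alpha)) for p in free}
    upper = {p: float(np.quantile(reps[p], 1.0 - alpha)) for p in free}
    return BootstrapCI(
        level=level, lower=lower, upper=upper, n_boot=n_boot, seed=seed,
        n_failed=n_failed,
    )


def save_fits(fits: Sequence[FitResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([f.to_dict() for f in fits], sort_keys=True, indent=1) + "\n"
    )
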