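"""Staged random-walk Metropolis calibration.

Gaussian priors, Gaussian observation likelihoods, per-parameter symmetric
Gaussian proposals with hard bounds, and the four-stage schedule used to
recalibrate the 14 key quantities:

  A. root specific conductance and the leaf vulnerability midpoint against
     biweekly midday xylem water potential;
  B. leaf nitrogen content, the Vcmax-nitrogen slope, and the vulnerability
     midpoint against a leaf gas-exchange response dataset (stage B's value
     of the midpoint is final);
  C. the two active berry sugar-import coefficients against berry dry
     weight;
  D. the four phloem-conductance coefficients against berry fresh weight
     and sugar concentration.

Each stage fixes the posterior means of earlier stages. Simulation
failures inside a likelihood score the proposal at -inf and are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .plant import (
    PlantParams,
    SeasonInputs,
    replay_berry_arrays,
    run_carbon_berry,
    simulate_hours,
    simulate_hydraulics,
)
from .canopy import build_canopy
from .plant import solve_hour

__all__ = [
    "McmcSpec",
    "Chain",
    "StageResult",
    "gaussian_loglik",
    "metropolis",
    "apply_params",
    "PARAM_SETTERS",
    "make_psi_xylem_loglik",
    "make_gas_exchange_loglik",
    "make_berry_loglik",
    "CalibrationStage",
    "run_stage",
    "staged_calibration",
    "standard_stages",
    "split_vintages",
    "DEFAULT_SIGMA_OBS",
]

log = logging.getLogger(__name__)

#: default observation-error standard deviations per stream
DEFAULT_SIGMA_OBS = {
    "psi_xylem_midday": 0.08,  # MPa
    "berry_fw_g": 0.05,  # g
    "berry_dw_g": 0.01,  # g
    "sugar_g_per_l": 8.0,  # g L-1
    "gs": 0.03,  # mol m-2 s-1
    "pn": 1.5,  # umol m-2 s-1
}


@dataclass(frozen=True)
class McmcSpec:
    """Sampler configuration for one stage."""

    param_names: tuple[str, ...]
    prior_mean: np.ndarray
    prior_sd: np.ndarray
    bounds: np.ndarray  # shape (k, 2)
    proposal_sd: np.ndarray | None = None  # default: 5% of prior_sd
    n_iter: int = 5000
    n_burn: int = 1000
    seed: int = 0
    #: adapt the proposal covariance to the chain history during burn-in
    #: only (frozen afterwards, so the post-burn-in kernel is Markovian)
    adapt: bool = False

    def __post_init__(self) -> None:
        k = len(self.param_names)
        pm = np.asarray(self.prior_mean, dtype=float)
        ps = np.asarray(self.prior_sd, dtype=float)
        b = np.asarray(self.bounds, dtype=float).reshape(k, 2)
        object.__setattr__(self, "prior_mean", pm)
        object.__setattr__(self, "prior_sd", ps)
        object.__setattr__(self, "bounds", b)
        if self.proposal_sd is not None:
            prop = np.asarray(self.proposal_sd, dtype=float)
            object.__setattr__(self, "proposal_sd", prop)
        if pm.shape != (k,) or ps.shape != (k,):
            raise ValueError("prior_mean/prior_sd must match param_names")
        if np.any(ps <= 0):
            raise ValueError("prior_sd must be > 0")
        if not np.all(np.isfinite(b)):
            raise ValueError("bounds must be finite")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")

    @property
    def proposals(self) -> np.ndarray:
        if self.proposal_sd is not None:
            return self.proposal_sd
        return 0.05 * self.prior_sd


@dataclass
class Chain:
    """Metropolis output: samples, log-posterior, acceptance bookkeeping."""

    samples: np.ndarray  # (n_iter, k)
    log_posterior: np.ndarray
    accepted: np.ndarray
    spec: McmcSpec

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def posterior_mean(self) -> np.ndarray:
        return self.samples[self.spec.n_burn :].mean(axis=0)

    def posterior_sd(self) -> np.ndarray:
        return self.samples[self.spec.n_burn :].std(axis=0, ddof=1)

    def map_estimate(self) -> np.ndarray:
        return self.samples[int(np.argmax(self.log_posterior))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.spec.param_names))
        df["log_posterior"] = self.log_posterior
        df["accepted"] = self.accepted
        df.index.name = "iteration"
        return df


def gaussian_loglik(obs, sim, sigma) -> float:
    """Sum of independent Gaussian log-densities of obs around sim.

    ``sigma`` may be a scalar or per-observation array; an empty
    observation set contributes 0.
    """
    o = np.asarray(obs, dtype=float)
    s = np.asarray(sim, dtype=float)
    if o.shape != s.shape:
        raise ValueError("obs and sim lengths differ")
    if o.size == 0:
        return 0.0
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), o.shape)
    if np.any(sig <= 0):
        raise ValueError("sigma must be > 0")
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * sig**2) - (o - s) ** 2 / (2.0 * sig**2)))


def metropolis(log_post: Callable[[np.ndarray], float], spec: McmcSpec) -> Chain:
    """Random-walk Metropolis with per-parameter Gaussian proposals.

    Proposals outside the bounds are rejected outright; otherwise accepted
    with probability min(1, exp(delta log-posterior)). Fully reproducible
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.param_names)
    x = np.clip(spec.prior_mean.copy(), spec.bounds[:, 0], spec.bounds[:, 1])
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError(f"log-posterior not finite at the prior mean: {lp}")
    prop_sd = spec.proposals
    chol: np.ndarray | None = None  # adaptive proposal Cholesky factor
    samples = np.empty((spec.n_iter, k))
    lps = np.empty(spec.n_iter)
    acc = np.zeros(spec.n_iter, dtype=bool)
    for i in range(spec.n_iter):
        if spec.adapt and 0 < i <= spec.n_burn and i % 200 == 0 and i >= 400:
            # burn-in-only adaptation: orient the proposal along the chain's
            # empirical covariance (standard 2.38^2/k scaling, regularized)
            hist = samples[max(0, i - 1200) : i]
            cov = np.cov(hist.T) + np.diag((0.1 * prop_sd) ** 2)
            try:
                chol = np.linalg.cholesky(cov * (2.38**2 / k))
            except np.linalg.LinAlgError:
                chol = None
        z = rng.normal(0.0, 1.0, size=k)
        cand = x + (chol @ z if chol is not None else prop_sd * z)
        u = rng.random()
        if np.all(cand >= spec.bounds[:, 0]) and np.all(cand <= spec.bounds[:, 1]):
            lp_cand = log_post(cand)
            if np.isfinite(lp_cand) and math.log(u) < lp_cand - lp:
                x, lp = cand, lp_cand
                acc[i] = True
        samples[i] = x
        lps[i] = lp
    return Chain(samples=samples, log_posterior=lps, accepted=acc, spec=spec)


# ---------------------------------------------------------------------------
# parameter plumbing


def _set_soil(attr):
    return lambda p, v: replace(p, soil=replace(p.soil, **{attr: v}))


def _set_gx(attr):
    return lambda p, v: replace(p, gx=replace(p.gx, **{attr: v}))


def _set_canopy(attr):
    return lambda p, v: replace(p, canopy=replace(p.canopy, **{attr: v}))


def _set_berry(attr):
    return lambda p, v: replace(p, berry=replace(p.berry, **{attr: v}))


PARAM_SETTERS: dict[str, Callable[[PlantParams, float], PlantParams]] = {
    "rsc": _set_soil("rsc"),
    "ks": _set_soil("ks"),
    "alpha_v": _set_soil("alpha_v"),
    "n": _set_soil("n"),
    "p": _set_soil("p"),
    "leafN_content": _set_canopy("leafN_content"),
    "slope_vcmax": _set_gx("slope_vcmax"),
    "psi50_leaf": _set_gx("psi50_leaf"),
    "vmax_berry": _set_berry("vmax_berry"),
    "km_berry": _set_berry("km_berry"),
    "lp_max": _set_berry("lp_max"),
    "lp_min": _set_berry("lp_min"),
    "fm_star": _set_berry("fm_star"),
    "k_lp": _set_berry("k_lp"),
}


def apply_params(params: PlantParams, names: Sequence[str], values: Sequence[float]) -> PlantParams:
    """Return a copy of ``params`` with the named quantities replaced."""
    for name, value in zip(names, values, strict=True):
        try:
            setter = PARAM_SETTERS[name]
        except KeyError:
            raise KeyError(f"unknown calibration parameter {name!r}") from None
        params = setter(params, float(value))
    return params


# ---------------------------------------------------------------------------
# stage likelihood factories


def make_psi_xylem_loglik(
    datasets: Sequence[tuple[SeasonInputs, pd.DataFrame]],
    base_params: PlantParams,
    param_names: Sequence[str],
    sigma: float = DEFAULT_SIGMA_OBS["psi_xylem_midday"],
    midday_hour: int = 15,
    solve_tol: float = 1e-4,
) -> Callable[[np.ndarray], float]:
    """Likelihood of midday xylem-potential observations.

    Each dataset is (season inputs, observation table with date/value).
    Only the observation hours are simulated (the steady-state network has
    no memory); warm starts are carried across proposals for speed, and the
    network tolerance (``solve_tol``, MPa) sits far below the observation
    noise.
    """
    prepared = []
    for inputs, obs in datasets:
        ts = pd.DatetimeIndex(
            [pd.Timestamp(d).normalize() + pd.Timedelta(hours=midday_hour) for d in obs["date"]]
        )
        prepared.append((inputs, ts, obs["value"].to_numpy(dtype=float), {}))

    def loglik(x: np.ndarray) -> float:
        params = apply_params(base_params, param_names, x)
        total = 0.0
        for inputs, ts, values, warm in prepared:
            states = simulate_hours(inputs, params, ts, warm_starts=warm, tol=solve_tol)
            sim = np.array([s.psi_xylem for s in states])
            total += gaussian_loglik(values, sim, sigma)
        return total

    return loglik


def make_gas_exchange_loglik(
    gx_data: pd.DataFrame,
    base_params: PlantParams,
    param_names: Sequence[str],
    sigma_gs: float = DEFAULT_SIGMA_OBS["gs"],
    sigma_pn: float = DEFAULT_SIGMA_OBS["pn"],
) -> Callable[[np.ndarray], float]:
    """Likelihood of a gas-exchange response dataset (gs, Pn vs predawn).

    Each record carries its own midday weather (tair, rh, rad) and soil
    water potential; the whole-plant midday solution is computed per record
    and the top-of-canopy leaf compared with the observed gs and Pn.
    """
    need = {"psi_predawn", "gs", "pn", "tair", "rh", "rad"}
    if not need <= set(gx_data.columns):
        raise ValueError(f"gas-exchange data needs columns {sorted(need)}")
    rows = gx_data.reset_index(drop=True)
    warm: dict[int, object] = {}

    def loglik(x: np.ndarray) -> float:
        params = apply_params(base_params, param_names, x)
        canopy = build_canopy(params.canopy)
        total = 0.0
        for i, r in rows.iterrows():
            hs = solve_hour(
                canopy,
                float(r["tair"]),
                float(r["rh"]),
                float(r["rad"]),
                float(r["psi_predawn"]),
                params,
                warm.get(i),
            )
            warm[i] = hs
            top = hs.leaf_states[0]
            total += gaussian_loglik([r["gs"]], [top.gs], sigma_gs)
            total += gaussian_loglik([r["pn"]], [top.an], sigma_pn)
        return total

    return loglik


_BERRY_ARRAY_INDEX = {"berry_fw_g": 0, "berry_dw_g": 1, "sugar_g_per_l": 2}


def make_berry_loglik(
    datasets: Sequence[tuple[SeasonInputs, pd.DataFrame]],
    base_params: PlantParams,
    param_names: Sequence[str],
    variables: Sequence[str],
    sigma_obs: dict[str, float] | None = None,
) -> Callable[[np.ndarray], float]:
    """Likelihood of weekly berry observations (DW and/or FW + [Sugar]).

    The hydraulic pass is simulated once per vintage under the base
    parameters (the berry coefficients do not feed back on plant water
    status) and only the carbon/berry chain is replayed per proposal.
    """
    sigma_obs = dict(DEFAULT_SIGMA_OBS, **(sigma_obs or {}))
    prepared = []
    for inputs, obs in datasets:
        hydro = simulate_hydraulics(inputs, base_params)
        per_var = []
        for var in variables:
            idx = _BERRY_ARRAY_INDEX[var]
            sub = obs[obs["variable"] == var]
            ts = pd.DatetimeIndex(
                [pd.Timestamp(d).normalize() + pd.Timedelta(hours=23) for d in sub["date"]]
            )
            pos = hydro.index.get_indexer(ts)
            if (pos < 0).any():
                raise ValueError(f"observation dates outside simulation for {var}")
            per_var.append((idx, pos, sub["value"].to_numpy(dtype=float), sigma_obs[var]))
        prepared.append((hydro, inputs.berry_init, per_var))

    def loglik(x: np.ndarray) -> float:
        params = apply_params(base_params, param_names, x)
        total = 0.0
        for hydro, berry_init, per_var in prepared:
            arrays = replay_berry_arrays(hydro, params, berry_init)
            for idx, pos, values, sigma in per_var:
                total += gaussian_loglik(values, arrays[idx][pos], sigma)
        return total

    return loglik


# ---------------------------------------------------------------------------
# stage orchestration


@dataclass
class CalibrationStage:
    """One calibration stage: sampler spec plus a likelihood factory.

    ``loglik_factory`` receives the parameter set produced by the earlier
    stages and returns the stage log-likelihood.
    """

    name: str
    spec: McmcSpec
    loglik_factory: Callable[[PlantParams], Callable[[np.ndarray], float]]


@dataclass
class StageResult:
    name: str
    chain: Chain
    posterior_mean: dict[str, float]
    posterior_sd: dict[str, float]
    map_estimate: dict[str, float]
    acceptance_rate: float


def run_stage(stage: CalibrationStage, params: PlantParams) -> StageResult:
    """Run one Metropolis stage; failures inside the likelihood score -inf."""
    loglik = stage.loglik_factory(params)
    spec = stage.spec

    def log_post(x: np.ndarray) -> float:
        lp = float(
            np.sum(
                -0.5 * np.log(2.0 * np.pi * spec.prior_sd**2)
                - (x - spec.prior_mean) ** 2 / (2.0 * spec.prior_sd**2)
            )
        )
        try:
            ll = loglik(x)
        except (ValueError, RuntimeError, FloatingPointError, OverflowError) as exc:
            log.debug("stage %s: proposal %s failed: %s", stage.name, x, exc)
            return -np.inf
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    chain = metropolis(log_post, spec)
    names = list(spec.param_names)
    return StageResult(
        name=stage.name,
        chain=chain,
        posterior_mean=dict(zip(names, chain.posterior_mean())),
        posterior_sd=dict(zip(names, chain.posterior_sd())),
        map_estimate=dict(zip(names, chain.map_estimate())),
        acceptance_rate=chain.acceptance_rate,
    )


def staged_calibration(
    stages: Sequence[CalibrationStage], base_params: PlantParams
) -> tuple[dict[str, StageResult], PlantParams]:
    """Run stages in order, fixing each stage's posterior means afterwards.

    Returns the per-stage results and the parameter set with all calibrated
    quantities set to their posterior means (later stages override shared
    parameters, so a vulnerability midpoint sampled in both stages A and B
    keeps the stage-B value).
    """
    results: dict[str, StageResult] = {}
    params = base_params
    for stage in stages:
        log.info("calibration stage %s: %s", stage.name, stage.spec.param_names)
        res = run_stage(stage, params)
        results[stage.name] = res
        params = apply_params(
            params, list(res.posterior_mean), list(res.posterior_mean.values())
        )
        log.info(
            "stage %s done: acceptance %.2f, posterior means %s",
            stage.name,
            res.acceptance_rate,
            res.posterior_mean,
        )
    return results, params


def standard_stages(
    psi_datasets: Sequence[tuple[SeasonInputs, pd.DataFrame]],
    gx_data: pd.DataFrame,
    berry_datasets: Sequence[tuple[SeasonInputs, pd.DataFrame]],
    base_params: PlantParams,
    seed: int = 0,
    n_iter: int = 5000,
    n_burn: int = 1000,
    sigma_obs: dict[str, float] | None = None,
) -> list[CalibrationStage]:
    """The four-stage schedule with priors centered on the current defaults."""
    sig = dict(DEFAULT_SIGMA_OBS, **(sigma_obs or {}))
    p = base_params

    def spec(names, means, sds, bounds, stage_seed):
        return McmcSpec(
            param_names=tuple(names),
            prior_mean=np.array(means),
            prior_sd=np.array(sds),
            bounds=np.array(bounds),
            n_iter=n_iter,
            n_burn=n_burn,
            seed=stage_seed,
        )

    stages = [
        CalibrationStage(
            "A",
            spec(
                ["rsc", "psi50_leaf"],
                [p.soil.rsc, p.gx.psi50_leaf],
                [0.3 * p.soil.rsc, 0.25],
                [[p.soil.rsc * 0.05, p.soil.rsc * 5.0], [-3.0, -0.8]],
                seed,
            ),
            lambda params: make_psi_xylem_loglik(
                psi_datasets, params, ["rsc", "psi50_leaf"], sig["psi_xylem_midday"]
            ),
        ),
        CalibrationStage(
            "B",
            spec(
                ["leafN_content", "slope_vcmax", "psi50_leaf"],
                [p.canopy.leafN_content, p.gx.slope_vcmax, p.gx.psi50_leaf],
                [0.25 * p.canopy.leafN_content, 0.25 * p.gx.slope_vcmax, 0.25],
                [[0.5, 4.0], [15.0, 100.0], [-3.0, -0.8]],
                seed + 1,
            ),
            lambda params: make_gas_exchange_loglik(
                gx_data, params, ["leafN_content", "slope_vcmax", "psi50_leaf"],
                sig["gs"], sig["pn"],
            ),
        ),
        CalibrationStage(
            "C",
            spec(
                ["vmax_berry", "km_berry"],
                [p.berry.vmax_berry, p.berry.km_berry],
                [0.3 * p.berry.vmax_berry, 0.3 * p.berry.km_berry],
                [
                    [p.berry.vmax_berry * 0.1, p.berry.vmax_berry * 10.0],
                    [p.berry.km_berry * 0.1, p.berry.km_berry * 10.0],
                ],
                seed + 2,
            ),
            lambda params: make_berry_loglik(
                berry_datasets, params, ["vmax_berry", "km_berry"],
                ["berry_dw_g"], sig,
            ),
        ),
        CalibrationStage(
            "D",
            spec(
                ["lp_max", "lp_min", "fm_star", "k_lp"],
                [p.berry.lp_max, p.berry.lp_min, p.berry.fm_star, p.berry.k_lp],
                [
                    0.3 * p.berry.lp_max,
                    0.3 * p.berry.lp_min,
                    0.3 * p.berry.fm_star,
                    0.3 * p.berry.k_lp,
                ],
                [
                    [p.berry.lp_max * 0.1, p.berry.lp_max * 10.0],
                    [p.berry.lp_min * 0.1, p.berry.lp_min * 10.0],
                    [0.3, 3.0],
                    [1.0, 20.0],
                ],
                seed + 3,
            ),
            lambda params: make_berry_loglik(
                berry_datasets, params, ["lp_max", "lp_min", "fm_star", "k_lp"],
                ["berry_fw_g", "sugar_g_per_l"], sig,
            ),
        ),
    ]
    return stages


def split_vintages(
    all_vintages: Sequence[str], calibration: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive calibration/validation split by vintage label."""
    all_list = list(all_vintages)
    cal = list(calibration)
    unknown = set(cal) - set(all_list)
    if unknown:
        raise ValueError(f"unknown vintages requested: {sorted(unknown)}")
    if len(set(cal)) != len(cal):
        raise ValueError("duplicate vintages in calibration set")
    val = [v for v in all_list if v not in set(cal)]
    return cal, val
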