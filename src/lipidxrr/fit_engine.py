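"""Stochastic global fitting of slab stacks to reflectivity curves.

The optical model is fit with differential evolution, a genetic-type
global minimizer well suited to the multimodal, fringe-dominated cost
landscapes of reflectometry (default strategy best/1/bin with mutation
dithered in (0.3, 0.9), crossover CR = 0.9, population 15× the number of
free parameters — dithering preserves diversity while the best-member
pull gives usable convergence on 10–16 dimensional stacks).  The
default objective is the unweighted mean squared residual of log₁₀R —
reflectivity spans many decades, so a log-space cost weights the Kiessig
fringes at high q on an equal footing with the plateau region.  A
χ²-weighted linear-space cost is available when point-wise uncertainties
are trusted.

Parameters are addressed by slot names derived from the template stack:
``slab{i}_d``, ``slab{i}_rho``, ``slab{i}_sigma`` (i counted from the
fronting side), ``backing_sigma``, plus the curve-level ``scale`` and
``background``.  Any slot without an explicit FitParameter stays fixed at
its template value — matching the usual refinement practice of holding
substrate and buffer densities at their known values.

Per-parameter uncertainties come from a residual bootstrap: resampled
log-residuals are added back to the best-fit model curve and each
synthetic data set is re-fit locally from the global optimum.
"""

from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .stack_model import LayerStack, ReflectivityCurve, _abeles_batch

__all__ = [
    "FitParameter",
    "FitConfig",
    "FitResult",
    "cost",
    "fit_stack",
    "parameter_uncertainty",
    "compare_models",
    "stack_slot_values",
    "build_stack",
]


@dataclass
class FitParameter:
    """One named degree of freedom (or pinned value) of the fit."""

    name: str
    value: float
    bounds: tuple[float, float] | None = None
    fixed: bool = False

    def __post_init__(self):
        if not self.fixed:
            if self.bounds is None:
                raise ValueError(f"free parameter {self.name!r} needs bounds")
            lo, hi = self.bounds
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"parameter {self.name!r}: invalid bounds {self.bounds}")
            if not lo <= self.value <= hi:
                raise ValueError(
                    f"parameter {self.name!r}: value {self.value} outside bounds"
                )


@dataclass
class FitConfig:
    """Optimizer and objective configuration."""

    seed: int = 0
    population_size: int = 15  # multiplier on the number of free parameters
    max_generations: int = 600
    cost: str = "log_unweighted"  # or "chi2_weighted"
    scale: FitParameter = field(
        default_factory=lambda: FitParameter("scale", 1.0, fixed=True)
    )
    background: FitParameter = field(
        default_factory=lambda: FitParameter("background", 0.0, (0.0, 1e-8))
    )
    strategy: str = "best1bin"
    mutation: float | tuple[float, float] = (0.3, 0.9)
    recombination: float = 0.9
    tol: float = 1e-8
    roughness_model: str = "nevot_croce"
    n_starts: int = 1  # independent DE starts; best result kept

    def __post_init__(self):
        if self.population_size <= 0 or self.max_generations <= 0:
            raise ValueError("population size and generation count must be positive")
        if self.cost not in ("log_unweighted", "chi2_weighted"):
            raise ValueError(f"unknown cost kind {self.cost!r}")
        if self.background.value < 0:
            raise ValueError("background must be >= 0")


@dataclass
class FitResult:
    """Best-fit stack plus provenance of the search that produced it."""

    stack: LayerStack
    values: dict[str, float]
    cost_value: float
    cost_kind: str
    n_function_evals: int
    seed: int
    param_names: list[str]
    bounds: dict[str, tuple[float, float]]
    fixed: list[str]
    scale: float
    background: float
    cost_history: list[float]
    curve_fingerprint: str
    uncertainties: dict[str, float] | None = None
    message: str = ""

    def as_dict(self) -> dict:
        out = {
            "cost": self.cost_value,
            "cost_kind": self.cost_kind,
            "seed": self.seed,
            "n_function_evals": self.n_function_evals,
            "scale": self.scale,
            "background": self.background,
            "curve_fingerprint": self.curve_fingerprint,
            "parameters": {
                name: {
                    "value": self.values[name],
                    "fixed": name in self.fixed,
                    "bounds": list(self.bounds.get(name, ())) or None,
                    "stderr": (self.uncertainties or {}).get(name),
                }
                for name in self.param_names
            },
        }
        return out


# ---------------------------------------------------------------------------
# Stack <-> named-slot plumbing
# ---------------------------------------------------------------------------


def stack_slot_values(stack: LayerStack) -> dict[str, float]:
    """All addressable slots of a stack, with their current values."""
    vals: dict[str, float] = {}
    for i, s in enumerate(stack.slabs):
        vals[f"slab{i}_d"] = s.thickness
        vals[f"slab{i}_rho"] = s.electron_density
        vals[f"slab{i}_sigma"] = s.roughness
    vals["backing_sigma"] = stack.backing_roughness
    return vals


def build_stack(template: LayerStack, values: dict[str, float]) -> LayerStack:
    """Copy of ``template`` with the named slots replaced by ``values``."""
    stack = copy.deepcopy(template)
    for name, v in values.items():
        if name in ("scale", "background"):
            continue
        if name == "backing_sigma":
            stack.backing_roughness = v
            continue
        kind = name.rsplit("_", 1)
        idx = int(kind[0].removeprefix("slab"))
        attr = {"d": "thickness", "rho": "electron_density", "sigma": "roughness"}[
            kind[1]
        ]
        setattr(stack.slabs[idx], attr, v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # candidate stacks may be transiently odd
        stack.validate()
    return stack


def _curve_fingerprint(curve: ReflectivityCurve) -> str:
    h = hashlib.sha256()
    h.update(curve.q.tobytes())
    h.update(curve.R.tobytes())
    if curve.dR is not None:
        h.update(curve.dR.tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def cost(
    curve: ReflectivityCurve,
    model_R: np.ndarray,
    config: FitConfig,
) -> float:
    """Objective value for a model curve against data.

    log_unweighted : mean over usable points of
        (log₁₀(scale·R_model + background) − log₁₀ R_data)².
    chi2_weighted  : mean of ((scale·R_model + background − R_data)/dR)².
    Non-positive data points are masked (with a warning) under the log cost.
    """
    model_R = np.asarray(model_R, dtype=float)
    if model_R.shape != curve.R.shape:
        raise ValueError("model and data lengths differ")
    scaled = config.scale.value * model_R + config.background.value
    if config.cost == "log_unweighted":
        mask = curve.R > 0
        if not np.all(mask):
            warnings.warn(
                f"masking {int((~mask).sum())} non-positive data points under "
                "log cost",
                stacklevel=2,
            )
        if not np.any(mask):
            raise ValueError("no usable (positive) data points")
        resid = np.log10(scaled[mask]) - np.log10(curve.R[mask])
        return float(np.mean(resid**2))
    if curve.dR is None:
        raise ValueError("chi2_weighted cost requires dR on the curve")
    return float(np.mean(((scaled - curve.R) / curve.dR) ** 2))


class _Objective:
    """Vectorized objective over the free-parameter vector(s)."""

    def __init__(self, curve, template, free_names, fixed_values, config):
        self.curve = curve
        self.config = config
        self.free_names = free_names
        self.n_evals = 0
        self.best_history: list[float] = []
        self._best = np.inf

        n_slabs = len(template.slabs)
        self.n_layers = n_slabs + 2
        base = stack_slot_values(template)
        base.update(fixed_values)
        self.base = base
        self.template = template
        # Positional index of each slot in the (rho, d, sigma) arrays.
        self.rho0 = np.empty(self.n_layers)
        self.rho0[0] = template.fronting.electron_density
        self.rho0[-1] = template.backing.electron_density
        for i in range(n_slabs):
            self.rho0[i + 1] = base[f"slab{i}_rho"]
        self.d0 = np.array([base[f"slab{i}_d"] for i in range(n_slabs)])
        self.sigma0 = np.array(
            [base[f"slab{i}_sigma"] for i in range(n_slabs)] + [base["backing_sigma"]]
        )
        self.scale0 = fixed_values.get("scale", config.scale.value)
        self.bg0 = fixed_values.get("background", config.background.value)
        mask = curve.R > 0
        if config.cost == "log_unweighted" and not np.all(mask):
            warnings.warn(
                f"masking {int((~mask).sum())} non-positive data points under log cost",
                stacklevel=3,
            )
        self.mask = mask
        self.logR_data = np.log10(curve.R[mask]) if np.any(mask) else None

    def model_batch(self, x: np.ndarray):
        """Reflectivity (S, nq) plus scale/background arrays for batch x (n, S)."""
        S = x.shape[1]
        rho = np.tile(self.rho0, (S, 1))
        d = np.tile(self.d0, (S, 1))
        sigma = np.tile(self.sigma0, (S, 1))
        scale = np.full(S, self.scale0)
        bg = np.full(S, self.bg0)
        n_slabs = len(self.d0)
        for k, name in enumerate(self.free_names):
            if name == "scale":
                scale = x[k]
            elif name == "background":
                bg = x[k]
            elif name == "backing_sigma":
                sigma[:, n_slabs] = x[k]
            else:
                head, kind = name.rsplit("_", 1)
                i = int(head.removeprefix("slab"))
                if kind == "d":
                    d[:, i] = x[k]
                elif kind == "rho":
                    rho[:, i + 1] = x[k]
                else:
                    sigma[:, i] = x[k]
        R = _abeles_batch(
            rho, d, sigma, self.curve.q,
            nevot_croce=self.config.roughness_model == "nevot_croce",
        )
        return R, scale, bg

    def __call__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[:, None]
        self.n_evals += x.shape[1]
        R, scale, bg = self.model_batch(x)
        scaled = scale[:, None] * R + bg[:, None]
        if self.config.cost == "log_unweighted":
            with np.errstate(divide="ignore"):
                resid = np.log10(scaled[:, self.mask]) - self.logR_data
            c = np.mean(resid**2, axis=1)
        else:
            c = np.mean(
                ((scaled - self.curve.R[None, :]) / self.curve.dR[None, :]) ** 2,
                axis=1,
            )
        c = np.where(np.isfinite(c), c, 1e30)  # reject non-finite candidates
        best = float(np.min(c))
        if best < self._best:
            self._best = best
        self.best_history.append(self._best)
        return c[0] if single else c


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _split_parameters(params, config):
    """Free/fixed bookkeeping across stack slots and curve-level parameters."""
    params = list(params)
    named = {p.name for p in params}
    # curve-level parameters come from the config unless overridden
    for extra in (config.scale, config.background):
        if extra.name not in named:
            params.append(extra)
    seen = set()
    free, fixed_values, bounds = [], {}, {}
    for p in params:
        if p.name in seen:
            raise ValueError(f"duplicate parameter {p.name!r}")
        seen.add(p.name)
        if p.fixed:
            fixed_values[p.name] = p.value
        else:
            free.append(p)
            bounds[p.name] = tuple(p.bounds)
    return free, fixed_values, bounds


def fit_stack(
    curve: ReflectivityCurve,
    template: LayerStack,
    params: list[FitParameter],
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Global fit of the named free parameters by differential evolution.

    Reproducible for a fixed ``config.seed``; fixed parameters and template
    slots without a FitParameter never move; the best-so-far cost recorded
    per objective call is non-increasing.
    """
    free, fixed_values, bounds = _split_parameters(params, config)
    if not free:
        raise ValueError("no free parameters: nothing to fit")
    known = set(stack_slot_values(template)) | {"scale", "background"}
    for p in free + [FitParameter(n, v, fixed=True) for n, v in fixed_values.items()]:
        if p.name not in known:
            raise ValueError(f"parameter {p.name!r} does not address any stack slot")

    free_names = [p.name for p in free]

    # A multimodal landscape occasionally traps a single DE population;
    # independent seeded starts make convergence robust while keeping the
    # whole search reproducible.
    opt = None
    total_evals = 0
    history: list[float] = []
    for start in range(max(1, config.n_starts)):
        objective = _Objective(curve, template, free_names, fixed_values, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            candidate = differential_evolution(
                objective,
                [bounds[n] for n in free_names],
                strategy=config.strategy,
                mutation=config.mutation,
                recombination=config.recombination,
                popsize=config.population_size,
                maxiter=config.max_generations,
                tol=config.tol,
                seed=(config.seed + start * 1000003) % (2**31 - 1),
                polish=True,
                init="latinhypercube",
                updating="deferred",
                vectorized=True,
            )
        total_evals += objective.n_evals
        history.extend(objective.best_history)
        if opt is None or candidate.fun < opt.fun:
            opt = candidate
    history = np.minimum.accumulate(history).tolist()

    best_values = dict(zip(free_names, np.asarray(opt.x, dtype=float)))
    all_values = stack_slot_values(template)
    all_values.update(fixed_values)
    all_values.update(best_values)
    stack = build_stack(template, all_values)
    scale = all_values.get("scale", config.scale.value)
    background = all_values.get("background", config.background.value)

    return FitResult(
        stack=stack,
        values=all_values,
        cost_value=float(opt.fun),
        cost_kind=config.cost,
        n_function_evals=total_evals,
        seed=config.seed,
        param_names=sorted(all_values),
        bounds=bounds,
        fixed=sorted(set(all_values) - set(free_names)),
        scale=float(scale),
        background=float(background),
        cost_history=history,
        curve_fingerprint=_curve_fingerprint(curve),
        message=str(opt.message),
    )


def parameter_uncertainty(
    result: FitResult,
    curve: ReflectivityCurve,
    template: LayerStack,
    config: FitConfig = FitConfig(),
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Residual-bootstrap 1-σ uncertainties for the free parameters.

    Log-space residuals of the best fit are resampled with replacement,
    added back to the best-fit model curve, and each synthetic curve is
    re-fit locally (Nelder-Mead-free gradient descent from the optimum).
    Fixed parameters report σ = 0.  Uncertainties shrink to zero with the
    noise level.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10 for a meaningful spread")
    rng = np.random.default_rng(seed)

    free_names = [n for n in result.param_names if n not in result.fixed]
    fixed_values = {n: result.values[n] for n in result.fixed}
    objective = _Objective(curve, template, free_names, fixed_values, config)
    x0 = np.array([result.values[n] for n in free_names])
    R_best, scale, bg = objective.model_batch(x0[:, None])
    model = scale[0] * R_best[0] + bg[0]

    mask = curve.R > 0
    log_model = np.log10(model[mask])
    resid = np.log10(curve.R[mask]) - log_model
    bnds = [result.bounds[n] for n in free_names]

    # refit in bounds-normalized units so thicknesses (Å) and densities
    # (e⁻·Å⁻³) see comparable finite-difference steps
    lo = np.array([b[0] for b in bnds])
    span = np.array([b[1] - b[0] for b in bnds])
    u0 = (x0 - lo) / span

    samples = np.empty((n_boot, len(free_names)))
    for b in range(n_boot):
        r_star = rng.choice(resid, size=resid.size, replace=True)
        R_star = curve.R.copy()
        R_star[mask] = 10.0 ** (log_model + r_star)
        boot_curve = ReflectivityCurve(curve.q, R_star, curve.dR)
        boot_obj = _Objective(boot_curve, template, free_names, fixed_values, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                lambda u: boot_obj(lo + span * u),
                u0,
                method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * len(free_names),
                options={"maxiter": 300},
            )
        samples[b] = lo + span * res.x

    sigma = {n: float(s) for n, s in zip(free_names, samples.std(axis=0, ddof=1))}
    for n in result.fixed:
        sigma[n] = 0.0
    result.uncertainties = sigma
    return sigma


def compare_models(
    curve: ReflectivityCurve,
    fits: list[FitResult],
    threshold: float = 0.10,
) -> tuple[FitResult, dict]:
    """Parsimony-based slab-count selection.

    Given fits of nested slab models (fewer slabs first) on the same data
    and cost, a larger model is retained only if it improves the cost by
    more than ``threshold`` (relative).  Ties favour the smaller model —
    an extra slab that does not improve the fit is physically
    uninformative.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fp = _curve_fingerprint(curve)
    for f in fits:
        if f.curve_fingerprint != fp:
            raise ValueError("fits were not performed on this curve")
        if f.cost_kind != fits[0].cost_kind:
            raise ValueError("fits use different cost functions")
    ordered = sorted(fits, key=lambda f: len(f.stack.slabs))
    selected = ordered[0]
    steps = []
    for f in ordered[1:]:
        improvement = (selected.cost_value - f.cost_value) / selected.cost_value
        accepted = improvement > threshold
        steps.append(
            {
                "n_slabs_small": len(selected.stack.slabs),
                "n_slabs_large": len(f.stack.slabs),
                "cost_small": selected.cost_value,
                "cost_large": f.cost_value,
                "relative_improvement": improvement,
                "threshold": threshold,
                "accepted_larger": bool(accepted),
            }
        )
        if accepted:
            selected = f
    report = {"selected_n_slabs": len(selected.stack.slabs), "comparisons": steps}
    return selected, report
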