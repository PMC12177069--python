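"""Gaussian-process mapping from stimulation settings to walking performance.

A Matérn-kernel GP (smoothness ν = 3/2, anisotropic length scales over
amplitude mA, frequency Hz and pulse width μs, inputs kept in raw device
units) is fitted to observed (setting, baseline-normalized WPI) pairs by
maximizing the log-marginal likelihood with restarted optimizers.  The
proposal policy is pure exploitation of both tails of the posterior mean:
the predicted-best and predicted-worst settings over a programming-
resolution grid are returned for testing alongside the clinical setting,
and the loop iterates fit → propose → evaluate until the evaluation
budget is spent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .types import StimSetting

log = logging.getLogger(__name__)

#: device-realistic programming increments for the proposal grid
DEFAULT_GRID_STEP = (0.1, 5.0, 10.0)  # mA, Hz, us


@dataclass
class GPRConfig:
    nu: float = 1.5
    length_scales: tuple[float, float, float] = (1.0, 20.0, 10.0)
    #: per-axis (mA, Hz, us) bounds; device-plausible scales keep the fit
    #: from collapsing to interpolation on small noisy designs
    length_scale_bounds: tuple = ((0.1, 50.0), (2.0, 1000.0), (2.0, 1000.0))
    n_restarts: int = 40
    noise_variance: float = 1e-2
    noise_bounds: tuple[float, float] = (1e-6, 1.0)
    signal_variance_bounds: tuple[float, float] = (1e-3, 1e3)
    seed: int = 0
    optimize: bool = True  # False pins all hyperparameters at their initial values

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if any(l <= 0 for l in self.length_scales):
            raise ValueError("length scales must be positive")
        if self.n_restarts < 1:
            raise ValueError("need at least one optimizer start")


def matern_cov(
    x1: Sequence[float],
    x2: Sequence[float],
    length_scales: Sequence[float],
    nu: float = 1.5,
) -> float:
    """Matérn covariance between two settings.

    Implements k(x_i, x_j) = 2^{1-ν}/Γ(ν) · (√(2ν) r)^ν · K_ν(√(2ν) r)
    where r is the Euclidean distance after per-axis scaling by the length
    scales and K_ν is the modified Bessel function of the second kind.
    The ν = 3/2 case reduces to (1 + √3 r)·exp(−√3 r).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    l = np.asarray(length_scales, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("inputs must have the same dimension")
    if np.any(l <= 0):
        raise ValueError("length scales must be positive")
    r = float(np.sqrt(np.sum(((x1 - x2) / l) ** 2)))
    if r < 1e-12:
        return 1.0
    z = np.sqrt(2.0 * nu) * r
    return float(2.0 ** (1.0 - nu) / gamma_fn(nu) * z**nu * kv(nu, z))


@dataclass
class GPRModel:
    """Fitted GP state."""

    X: np.ndarray  # (n, 3) settings
    y: np.ndarray  # (n,) targets (original scale)
    y_mean: float
    gp: GaussianProcessRegressor
    length_scales: np.ndarray
    noise_variance: float
    log_marginal_likelihood: float


def fit_gpr(
    settings: np.ndarray | Sequence[StimSetting],
    wpi: Sequence[float],
    config: GPRConfig | None = None,
) -> GPRModel:
    """Fit the GP by restarted maximization of the log-marginal likelihood.

    Targets are centered by subtracting their mean before fitting (the
    mean is restored at prediction); observation noise is a fitted
    hyperparameter (WhiteKernel).
    """
    config = config or GPRConfig()
    X = _as_matrix(settings)
    y = np.asarray(wpi, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("settings and targets must have equal length")
    if X.shape[0] < 3 or np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need >= 3 observations spanning >= 2 distinct settings")
    y_mean = float(np.mean(y))
    fixed = not config.optimize
    kernel = ConstantKernel(
        1.0, "fixed" if fixed else config.signal_variance_bounds
    ) * Matern(
        length_scale=np.asarray(config.length_scales, dtype=float),
        length_scale_bounds="fixed" if fixed else config.length_scale_bounds,
        nu=config.nu,
    ) + WhiteKernel(
        config.noise_variance, "fixed" if fixed else config.noise_bounds
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        optimizer=None if fixed else "fmin_l_bfgs_b",
        n_restarts_optimizer=config.n_restarts - 1,
        normalize_y=False,
        random_state=config.seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # noise level pinned at its lower bound is expected for noise-free data
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y - y_mean)
    k = gp.kernel_
    return GPRModel(
        X=X,
        y=y,
        y_mean=y_mean,
        gp=gp,
        length_scales=np.atleast_1d(k.k1.k2.length_scale).astype(float),
        noise_variance=float(k.k2.noise_level),
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
    )


def predict(model: GPRModel, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD at the grid points (original target scale)."""
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    mean, sd = model.gp.predict(grid, return_std=True)
    return mean + model.y_mean, np.maximum(sd, 0.0)


@dataclass
class SettingsProposal:
    best: StimSetting
    worst: StimSetting
    clinical: StimSetting
    predicted: dict[str, tuple[float, float]]  # name -> (mean, sd)


def _as_matrix(settings) -> np.ndarray:
    if isinstance(settings, np.ndarray):
        return np.atleast_2d(settings.astype(float))
    return np.array([s.as_array() for s in settings], dtype=float)


def settings_grid(
    safe_box: np.ndarray, step: Sequence[float] = DEFAULT_GRID_STEP
) -> np.ndarray:
    """Lexicographically ordered programming grid over the safe box."""
    box = np.asarray(safe_box, dtype=float)
    axes = [
        np.arange(box[i, 0], box[i, 1] + 1e-9, step[i]) for i in range(3)
    ]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return g


def propose_settings(
    model: GPRModel,
    safe_box: np.ndarray,
    clinical: StimSetting,
    step: Sequence[float] = DEFAULT_GRID_STEP,
) -> SettingsProposal:
    """Predicted-best and predicted-worst settings over the safe box.

    The grid is enumerated in ascending (amplitude, frequency, pulse
    width) order, so exact ties resolve toward lower amplitude, then
    lower frequency.
    """
    grid = settings_grid(safe_box, step)
    mean, sd = predict(model, grid)
    i_best = int(np.argmax(mean))  # first max in lexicographic order
    i_worst = int(np.argmin(mean))
    best = StimSetting.from_array(grid[i_best])
    worst = StimSetting.from_array(grid[i_worst])
    mc, sc = predict(model, clinical.as_array()[None, :])
    return SettingsProposal(
        best=best,
        worst=worst,
        clinical=clinical,
        predicted={
            "best": (float(mean[i_best]), float(sd[i_best])),
            "worst": (float(mean[i_worst]), float(sd[i_worst])),
            "clinical": (float(mc[0]), float(sc[0])),
        },
    )


def axis_design(clinical: StimSetting, safe_box: np.ndarray) -> list[StimSetting]:
    """Clinic-style initial design: vary one parameter axis at a time.

    Mirrors the programming protocol of testing, besides the clinical
    setting, the amplitude extremes of the safe range, a low (60 Hz) and a
    high stimulation frequency, and both pulse-width limits, keeping the
    other parameters at their clinical values (7 settings total).
    """
    box = np.asarray(safe_box, dtype=float)
    a, f, p = clinical.amplitude_mA, clinical.frequency_Hz, clinical.pulse_width_us
    lo_f = max(60.0, box[1, 0])
    pts = [
        clinical,
        StimSetting(box[0, 0], f, p),
        StimSetting(box[0, 1], f, p),
        StimSetting(a, lo_f, p),
        StimSetting(a, box[1, 1], p),
        StimSetting(a, f, box[2, 0]),
        StimSetting(a, f, box[2, 1]),
    ]
    seen, out = set(), []
    for s in pts:
        key = tuple(np.round(s.as_array(), 6))
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def initial_design(
    clinical: StimSetting, safe_box: np.ndarray, n_extra: int = 4, seed: int = 0
) -> list[StimSetting]:
    """Axis design plus seeded Latin-hypercube interior points.

    The combined design (7 axis settings + ``n_extra`` space-filling
    points, 11 by default) mirrors the number of configurations tested in
    clinic before the model starts proposing settings.
    """
    out = axis_design(clinical, safe_box)
    box = np.asarray(safe_box, dtype=float)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if n_extra > 0:
        perm = np.stack([rng.permutation(n_extra) for _ in range(3)], axis=1)
        for i in range(n_extra):
            u = (perm[i] + rng.uniform(size=3)) / n_extra
            out.append(StimSetting.from_array(box[:, 0] + (box[:, 1] - box[:, 0]) * u))
    return out


@dataclass
class OptimizationHistory:
    settings: list[StimSetting] = field(default_factory=list)
    observed: list[float] = field(default_factory=list)
    iterations: list[dict] = field(default_factory=list)
    final_proposal: SettingsProposal | None = None
    aborted: bool = False

    @property
    def running_best(self) -> np.ndarray:
        return np.maximum.accumulate(np.asarray(self.observed, dtype=float))

    @property
    def best_setting(self) -> StimSetting:
        return self.settings[int(np.argmax(self.observed))]


def run_optimization_loop(
    oracle: Callable[[StimSetting], float],
    config: GPRConfig,
    initial_design: Sequence[StimSetting],
    budget: int,
    safe_box: np.ndarray,
    step: Sequence[float] = DEFAULT_GRID_STEP,
) -> OptimizationHistory:
    """Iterative optimization: fit → propose best/worst → evaluate → augment.

    ``oracle`` evaluates one setting (truth plus observation noise); every
    call counts toward ``budget``.  Each iteration tests the proposed best
    and worst settings and re-tests the clinical setting, mirroring a
    clinic visit.  The loop ends when the budget is spent; a final model
    fit provides ``final_proposal``.
    """
    if len(initial_design) < 3:
        raise ValueError("initial design needs >= 3 settings")
    clinical = next((s for s in initial_design if s.clinical), None)
    if clinical is None:
        raise ValueError("initial design must include the clinical setting")
    hist = OptimizationHistory()

    def _evaluate(s: StimSetting) -> bool:
        if len(hist.observed) >= budget:
            return False
        try:
            v = float(oracle(s))
        except Exception as exc:  # oracle failure aborts with partial history
            log.error("oracle failed at %s: %s", s, exc)
            hist.aborted = True
            return False
        hist.settings.append(s)
        hist.observed.append(v)
        return True

    for s in initial_design:
        if not _evaluate(s):
            break
    while len(hist.observed) < budget and not hist.aborted:
        model = fit_gpr(hist.settings, hist.observed, config)
        prop = propose_settings(model, safe_box, clinical, step)
        hist.iterations.append(
            {
                "n_observed": len(hist.observed),
                "proposal": prop,
                "length_scales": model.length_scales.tolist(),
                "lml": model.log_marginal_likelihood,
            }
        )
        for s in (prop.best, prop.worst, clinical):
            if not _evaluate(s):
                break
    if not hist.aborted:
        model = fit_gpr(hist.settings, hist.observed, config)
        hist.final_proposal = propose_settings(model, safe_box, clinical, step)
    return hist
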