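"""Nonlinear least-squares fitting of thin-layer models and model ranking.

The central objects follow the Model/Results convention: build a
:class:`ThinLayerModel` from a moisture-ratio series (or a
:class:`~drykin.curves.DryingRun`), call :meth:`~ThinLayerModel.fit`, and
receive a :class:`ThinLayerResults` carrying the coefficient estimates,
the three goodness-of-fit statistics used for model discrimination
(R-squared, reduced chi-square, RMSE) and a ``summary()`` table.

Fit statistics
--------------
With observed MR values Y_i, predictions Yhat_i, N observations and z
fitted parameters:

    R^2        = 1 - SS_res / SS_tot
    RMSE       = sqrt(SS_res / N)
    chi^2_red  = SS_res / (N - z)

Optimisation is bounded trust-region least squares with a small
deterministic multi-start (jittered initial guesses, fixed seed); the best
objective wins, so refits are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy.optimize import least_squares

from .curves import DryingRun, RatioSeries, moisture_from_weights, moisture_ratio
from .models import ModelParams, get_model_spec, MODEL_IDS, evaluate

__all__ = [
    "GoodnessOfFit",
    "goodness_of_fit",
    "ThinLayerModel",
    "ThinLayerResults",
    "fit_model",
    "ModelRanking",
    "rank_models",
    "DEFAULT_SEED",
    "DEFAULT_N_STARTS",
]

DEFAULT_SEED = 1405
DEFAULT_N_STARTS = 5

# Relative tolerance under which two fits' criteria are considered tied;
# ties go to the more parsimonious model, then to the model name.  Needed
# because verma (g free) and diffusion_approach (g = k*b) span the same
# function family, so their converged objectives differ only by optimizer
# round-off.
_TIE_RTOL = 1e-6


@dataclass(frozen=True)
class GoodnessOfFit:
    r2: float
    chi2_reduced: float
    rmse: float
    n_obs: int
    n_params: int
    zero_variance: bool = False


def goodness_of_fit(observed, predicted, n_params: int) -> GoodnessOfFit:
    """R-squared, reduced chi-square and RMSE of predictions vs observations.

    Raises if there are no residual degrees of freedom.  A zero-variance
    observation vector makes R-squared undefined; it is returned as NaN with
    ``zero_variance=True`` rather than raising, so rankings can flag it.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    n = len(y)
    if n <= n_params:
        raise ValueError(f"need more than {n_params} observations, got {n}")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    zero_var = ss_tot == 0.0
    r2 = float("nan") if zero_var else 1.0 - ss_res / ss_tot
    return GoodnessOfFit(
        r2=r2,
        chi2_reduced=ss_res / (n - n_params),
        rmse=float(np.sqrt(ss_res / n)),
        n_obs=n,
        n_params=n_params,
        zero_variance=zero_var,
    )


class ThinLayerModel:
    """A thin-layer drying model bound to one moisture-ratio dataset.

    Parameters
    ----------
    times : array-like
        Observation times, minutes, strictly increasing.
    mr : array-like
        Observed moisture ratio at each time, in [0, 1.05].
    model : str
        One of the seven registered model ids
        (default ``"diffusion_approach"``).

    Examples
    --------
    >>> res = ThinLayerModel(times, mr, model="page").fit()
    >>> res.params.as_dict()["k"]
    """

    def __init__(self, times, mr, model: str = "diffusion_approach"):
        self.spec = get_model_spec(model)
        self.times = np.asarray(times, dtype=float)
        self.mr = np.asarray(mr, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.mr.shape:
            raise ValueError("times and mr must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.mr < 0) | (self.mr > 1.05)):
            raise ValueError("moisture ratio values must lie in [0, 1.05]")
        if len(self.times) <= self.spec.n_params:
            raise ValueError(
                f"{self.spec.model_id} has {self.spec.n_params} parameters; "
                f"need at least {self.spec.n_params + 1} observations, got {len(self.times)}"
            )

    @classmethod
    def from_run(cls, run: DryingRun, model: str = "diffusion_approach") -> "ThinLayerModel":
        """Build from a drying run via moisture content and moisture ratio."""
        ratio = moisture_ratio(moisture_from_weights(run))
        return cls(ratio.times, ratio.mr, model=model)

    @classmethod
    def from_ratio(cls, ratio: RatioSeries, model: str = "diffusion_approach") -> "ThinLayerModel":
        return cls(ratio.times, ratio.mr, model=model)

    # -- fitting -----------------------------------------------------------

    def _starts(self, initial, n_starts: int, seed: int) -> list[np.ndarray]:
        spec = self.spec
        x0 = np.asarray(initial if initial is not None else spec.default_initial, dtype=float)
        starts = [x0]
        # Degenerate-submodel starts let nested fits never lose to their
        # restriction (e.g. diffusion approach with b=1 collapses to newton).
        if spec.model_id == "diffusion_approach":
            starts.append(np.array([x0[0], x0[1], 1.0]))
        elif spec.model_id == "verma":
            starts.append(np.array([x0[0], x0[1], x0[1]* (1 - 1e-3)]))
        elif spec.model_id in ("henderson_pabis", "logarithmic"):
            s = x0.copy()
            s[0] = 1.0
            if spec.model_id == "logarithmic":
                s[2] = 0.0
            starts.append(s)
        rng = np.random.default_rng(seed)
        rate_like = {"k", "g", "b"}
        while len(starts) < n_starts:
            jit = x0.copy()
            for i, name in enumerate(spec.parameter_names):
                if name in rate_like:
                    jit[i] *= np.exp(rng.uniform(np.log(0.5), np.log(1.5)))
                else:
                    jit[i] += rng.uniform(-0.15, 0.15)
            starts.append(jit)
        return starts

    def fit(
        self,
        initial=None,
        bounds=None,
        n_starts: int = DEFAULT_N_STARTS,
        seed: int = DEFAULT_SEED,
    ) -> "ThinLayerResults":
        """Bounded multi-start least squares; returns the best converged fit.

        If no start converges the results object carries
        ``converged=False`` and the best attempt found — never a silent
        success.
        """
        spec = self.spec
        bnds = tuple(bounds) if bounds is not None else spec.default_bounds
        lo = np.array([b[0] for b in bnds])
        hi = np.array([b[1] for b in bnds])

        def residuals(x: np.ndarray) -> np.ndarray:
            return evaluate(ModelParams(spec.model_id, tuple(x)), self.times) - self.mr

        best_x, best_cost, converged = None, np.inf, False
        for x0 in self._starts(initial, n_starts, seed):
            x0c = np.clip(x0, lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    residuals, x0c, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:
                continue
            if sol.cost < best_cost:
                best_x, best_cost = sol.x, sol.cost
                converged = converged or bool(sol.success)
        if best_x is None:
            best_x = np.clip(
                np.asarray(initial if initial is not None else spec.default_initial, float),
                lo, hi,
            )
            converged = False
        params = ModelParams(spec.model_id, tuple(best_x))
        predicted = evaluate(params, self.times)
        gof = goodness_of_fit(self.mr, predicted, spec.n_params)
        return ThinLayerResults(
            model=self, params=params, predicted=predicted, gof=gof, converged=converged,
        )


@dataclass(frozen=True)
class ThinLayerResults:
    """Fit of one thin-layer model: coefficients, statistics, predictions."""

    model: ThinLayerModel
    params: ModelParams
    predicted: npt.NDArray[np.float64]
    gof: GoodnessOfFit
    converged: bool

    @property
    def r2(self) -> float:
        return self.gof.r2

    @property
    def chi2_reduced(self) -> float:
        return self.gof.chi2_reduced

    @property
    def rmse(self) -> float:
        return self.gof.rmse

    @property
    def n_obs(self) -> int:
        return self.gof.n_obs

    @property
    def ss_res(self) -> float:
        return self.gof.chi2_reduced * (self.gof.n_obs - self.gof.n_params)

    def predict(self, times) -> npt.NDArray[np.float64]:
        return evaluate(self.params, times)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Thin-layer drying model: {spec.model_id}",
            f"  observations: {self.n_obs}   converged: {self.converged}",
            "  coefficients:",
        ]
        for name, value in self.params.as_dict().items():
            unit = " 1/min" if name in ("k", "g") else ""
            lines.append(f"    {name:>2} = {value:.6g}{unit}")
        lines += [
            f"  R^2          = {self.r2:.6f}",
            f"  reduced chi2 = {self.chi2_reduced:.3e}",
            f"  RMSE         = {self.rmse:.3e}",
        ]
        return "\n".join(lines)


def fit_model(
    model_id: str,
    times,
    mr,
    initial=None,
    bounds=None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
) -> ThinLayerResults:
    """Functional wrapper: fit one named model to a moisture-ratio series."""
    return ThinLayerModel(times, mr, model=model_id).fit(
        initial=initial, bounds=bounds, n_starts=n_starts, seed=seed
    )


@dataclass(frozen=True)
class ModelRanking:
    """Ordered fits of all seven models for one drying curve."""

    ranked: tuple[tuple[str, ThinLayerResults], ...]
    best: str
    failures: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.ranked)

    def summary(self) -> str:
        lines = [f"{'model':<20} {'R^2':>10} {'red. chi2':>12} {'RMSE':>10}  flag"]
        for model_id, res in self.ranked:
            flag = "" if res.converged and not res.gof.zero_variance else "  *"
            lines.append(
                f"{model_id:<20} {res.r2:>10.5f} {res.chi2_reduced:>12.3e} "
                f"{res.rmse:>10.3e}{flag}"
            )
        for model_id, err in self.failures.items():
            lines.append(f"{model_id:<20} failed: {err}")
        lines.append(f"best: {self.best}")
        return "\n".join(lines)


def rank_models(times, mr, model_ids=None, seed: int = DEFAULT_SEED) -> ModelRanking:
    """Fit every registered model and rank by R^2, chi^2, RMSE.

    Primary sort is descending R^2; near-ties (relative differences below
    1e-6) fall through to ascending reduced chi-square and RMSE, then to
    fewer parameters and the model name, so the ordering is deterministic
    even when two model families coincide.  Non-converged or
    zero-variance fits rank last and are flagged; a model whose fit raises
    is recorded in ``failures`` without aborting the ranking.
    """
    ids = tuple(model_ids) if model_ids is not None else MODEL_IDS
    fits: list[tuple[str, ThinLayerResults]] = []
    failures: dict[str, str] = {}
    for model_id in ids:
        try:
            fits.append((model_id, fit_model(model_id, times, mr, seed=seed)))
        except Exception as exc:  # propagate per-model, keep ranking alive
            failures[model_id] = str(exc)
    if not fits:
        raise ValueError("no model could be fitted: " + "; ".join(failures.values()))

    def sort_key(item: tuple[str, ThinLayerResults]):
        model_id, res = item
        usable = res.converged and not res.gof.zero_variance and np.isfinite(res.r2)
        # quantise criteria so that optimizer round-off does not decide order
        def q(v: float) -> float:
            if not np.isfinite(v):
                return np.inf
            scale = max(abs(v), 1e-12)
            return round(v / (scale * _TIE_RTOL)) * (scale * _TIE_RTOL)
        return (
            0 if usable else 1,
            -q(res.r2) if usable else 0.0,
            q(res.chi2_reduced),
            q(res.rmse),
            res.gof.n_params,
            model_id,
        )

    ranked = tuple(sorted(fits, key=sort_key))
    return ModelRanking(ranked=ranked, best=ranked[0][0], failures=failures)
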