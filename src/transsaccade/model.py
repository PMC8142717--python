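"""Maximum-likelihood fitting of the resource-limited observer.

The entry point follows the statsmodels idiom: build an
:class:`ObserverModel` from a trial table, call :meth:`ObserverModel.fit`,
and read estimates, standard errors and a summary table off the returned
:class:`ObserverFitResults`.

Identifiability depends on the design the trials come from. Set-size
variation (Experiment 1) identifies the precision--share power law
(kappa1, alpha); cue conditions (Experiment 2) identify p_cue; single-view
conditions pin kappa_pre and kappa_post separately. Tables mixing both
designs identify all five parameters; with Experiment-1-only data p_cue
is automatically held fixed (no cued trials exist to inform it).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .alignment import align
from .integration import sd_to_kappa
from .circstats import circ_sd
from .design import SHIFT_MAGNITUDE_DEG
from .likelihood import both_density_grid, interp_circular, vm_logpdf, TWO_PI
from .observer import ObserverParams, simulate_responses

__all__ = ["ObserverModel", "ObserverFitResults", "fit_observer"]

_PARAM_NAMES = ("kappa1", "alpha", "p_cue", "kappa_post", "lapse")

_KAPPA_LO, _KAPPA_HI = 0.2, 64.0
_ALPHA_LO, _ALPHA_HI = 0.05, 4.0
_LAPSE_HI = 0.5


def _expit(x):
    return special.expit(x)


def _logit(p):
    return float(special.logit(p))


def _to_transformed(p: ObserverParams) -> np.ndarray:
    return np.array(
        [
            np.log(np.clip(p.kappa1, _KAPPA_LO, _KAPPA_HI)),
            np.log(np.clip(p.alpha, _ALPHA_LO, _ALPHA_HI)),
            _logit(np.clip((p.p_cue - 0.25) / 0.75, 1e-6, 1 - 1e-6)),
            np.log(np.clip(p.kappa_post, _KAPPA_LO, _KAPPA_HI)),
            _logit(np.clip(p.lapse / _LAPSE_HI, 1e-9, 1 - 1e-9)),
        ]
    )


def _from_transformed(t: np.ndarray) -> dict:
    return {
        "kappa1": float(np.exp(t[0])),
        "alpha": float(np.exp(t[1])),
        "p_cue": float(0.25 + 0.75 * _expit(t[2])),
        "kappa_post": float(np.exp(t[3])),
        "lapse": float(_LAPSE_HI * _expit(t[4])),
    }


def _jacobian_natural(t: np.ndarray) -> np.ndarray:
    """d(natural)/d(transformed), elementwise."""
    s2 = _expit(t[2])
    s4 = _expit(t[4])
    return np.array(
        [
            np.exp(t[0]),
            np.exp(t[1]),
            0.75 * s2 * (1 - s2),
            np.exp(t[3]),
            _LAPSE_HI * s4 * (1 - s4),
        ]
    )


_BOUNDS = [
    (np.log(_KAPPA_LO), np.log(_KAPPA_HI)),
    (np.log(_ALPHA_LO), np.log(_ALPHA_HI)),
    (-10.0, 10.0),
    (np.log(_KAPPA_LO), np.log(_KAPPA_HI)),
    (-14.0, 6.0),
]


@dataclass
class _Cell:
    presentation: str
    share_kind: str  # "fixed", "cued" or "uncued"
    set_size: int
    errors_rad: np.ndarray

    def share(self, p_cue: float) -> float:
        if self.share_kind == "cued":
            return p_cue
        if self.share_kind == "uncued":
            return (1.0 - p_cue) / 3.0
        return 1.0 / self.set_size


class ObserverModel:
    """Likelihood model of the resource-limited observer for a trial table.

    Parameters
    ----------
    trials : DataFrame
        Trial table with responses; aligned-error columns are computed on
        the fly when absent.
    n_latent : int
        Latent-grid size per dimension for the BOTH-trial double
        integral (periodic trapezoid rule).
    n_response_grid : int
        Response-grid size on which the BOTH-trial marginal density is
        tabulated before interpolation at the observed errors.
    """

    def __init__(self, trials: pd.DataFrame, n_latent: int = 72, n_response_grid: int = 144):
        if "error_aligned_deg" not in trials.columns:
            trials = align(trials)
        self.n_latent = int(n_latent)
        self.r_grid = np.linspace(-np.pi, np.pi, int(n_response_grid), endpoint=False)
        self.delta_rad = np.radians(SHIFT_MAGNITUDE_DEG)
        self.cells = self._build_cells(trials)
        self.nobs = int(sum(c.errors_rad.size for c in self.cells))

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kwargs) -> "ObserverModel":
        return cls(trials, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ObserverModel":
        return cls(pd.read_csv(path), **kwargs)

    @staticmethod
    def _build_cells(trials: pd.DataFrame) -> list[_Cell]:
        t = trials.dropna(subset=["response_deg"]).copy()
        cue = t["cue_condition"].astype(str)
        probed_is_cued = t["probed_location"].astype(str) == t["cued_location"].astype(str)
        kind = np.where(
            cue == "valid", "cued", np.where(cue == "invalid", "uncued", "fixed")
        )
        t["_kind"] = kind
        cells = []
        for (pres, k, n), sub in t.groupby(["presentation", "_kind", "set_size"]):
            cells.append(
                _Cell(
                    presentation=str(pres),
                    share_kind=str(k),
                    set_size=int(n),
                    errors_rad=np.radians(sub["error_aligned_deg"].to_numpy(dtype=float)),
                )
            )
        if not cells:
            raise ValueError("no trials with responses")
        return cells

    # likelihood ---------------------------------------------------------

    def loglike(self, params: ObserverParams) -> float:
        """Log-likelihood of all responses under the observer model."""
        params.validate()
        ll = 0.0
        lapse = params.lapse
        for cell in self.cells:
            kp = params.kappa1 * cell.share(params.p_cue) ** params.alpha
            if cell.presentation == "pre_only":
                f = np.exp(vm_logpdf(cell.errors_rad, 0.0, kp))
            elif cell.presentation == "post_only":
                f = np.exp(vm_logpdf(cell.errors_rad, self.delta_rad, params.kappa_post))
            else:
                grid = both_density_grid(
                    kp, params.kappa_post, self.delta_rad, self.r_grid, self.n_latent
                )
                f = interp_circular(cell.errors_rad, self.r_grid, grid)
            mixed = (1.0 - lapse) * f + lapse / TWO_PI
            ll += float(np.log(np.maximum(mixed, 1e-300)).sum())
        return ll

    # starting values ----------------------------------------------------

    def _moment_start(self, p_cue0: float = 0.5) -> ObserverParams:
        """Method-of-moments initialization from single-view cells.

        Falls back to a coarse grid search over (kappa1, alpha,
        kappa_post) when the table has no single-view conditions (e.g.
        Experiment 1, where every trial shows both views).
        """
        post_sds = [
            circ_sd(np.degrees(c.errors_rad))
            for c in self.cells
            if c.presentation == "post_only"
        ]
        pre_cells = [c for c in self.cells if c.presentation == "pre_only"]
        kq = np.clip(sd_to_kappa(float(np.mean(post_sds))), _KAPPA_LO, _KAPPA_HI) if post_sds else None
        if pre_cells:
            shares = np.array([c.share(p_cue0) for c in pre_cells])
            kappas = np.array(
                [
                    np.clip(sd_to_kappa(circ_sd(np.degrees(c.errors_rad))), _KAPPA_LO, _KAPPA_HI)
                    for c in pre_cells
                ]
            )
            if len(pre_cells) >= 2 and np.unique(shares).size >= 2:
                slope, intercept = np.polyfit(np.log(shares), np.log(kappas), 1)
                alpha = float(np.clip(slope, _ALPHA_LO, _ALPHA_HI))
                kappa1 = float(np.clip(np.exp(intercept), _KAPPA_LO, _KAPPA_HI))
            else:
                alpha = 1.0
                kappa1 = float(np.clip(kappas[0] / shares[0], _KAPPA_LO, _KAPPA_HI))
            return ObserverParams(
                kappa1=kappa1,
                alpha=alpha,
                p_cue=p_cue0,
                kappa_post=float(kq if kq is not None else 4.0),
                lapse=0.02,
            )
        return self._grid_start(p_cue0, kq)

    def _grid_start(self, p_cue0: float, kq: float | None) -> ObserverParams:
        best, best_ll = None, -np.inf
        kq_grid = [kq] if kq is not None else [1.0, 2.0, 4.0, 8.0, 16.0]
        for k1 in (2.0, 4.0, 8.0, 16.0, 32.0):
            for a in (0.6, 1.0, 1.6):
                for kqq in kq_grid:
                    cand = ObserverParams(
                        kappa1=k1, alpha=a, p_cue=p_cue0, kappa_post=kqq, lapse=0.02
                    )
                    ll = self.loglike(cand)
                    if ll > best_ll:
                        best, best_ll = cand, ll
        return best

    # fitting ------------------------------------------------------------

    def fit(
        self,
        start: ObserverParams | None = None,
        seed: int = 0,
        maxiter: int = 200,
        compute_bse: bool = True,
    ) -> "ObserverFitResults":
        """Maximize the log-likelihood (L-BFGS-B on transformed parameters).

        Parameters without information in the data are held at their
        starting values: p_cue is frozen when no cued/uncued trials
        exist, alpha when only one resource share occurs, kappa_post when
        no trial includes the post-saccadic view.
        """
        kinds = {c.share_kind for c in self.cells}
        shares0 = {
            (c.share_kind, c.set_size) for c in self.cells if c.presentation != "post_only"
        }
        has_post = any(c.presentation != "pre_only" for c in self.cells)
        free = {
            "kappa1": any(c.presentation != "post_only" for c in self.cells),
            "alpha": len(shares0) >= 2,
            "p_cue": bool(kinds & {"cued", "uncued"}),
            "kappa_post": has_post,
            "lapse": True,
        }
        if start is None:
            start = self._moment_start()
        start = start.validate()
        t_full = _to_transformed(start)
        free_idx = [i for i, name in enumerate(_PARAM_NAMES) if free[name]]
        nfev = 0

        def negll(t_free):
            nonlocal nfev
            nfev += 1
            t = t_full.copy()
            t[free_idx] = t_free
            p = replace(start, **_from_transformed(t))
            return -self.loglike(p)

        res = optimize.minimize(
            negll,
            t_full[free_idx],
            method="L-BFGS-B",
            bounds=[_BOUNDS[i] for i in free_idx],
            options={"maxiter": maxiter},
        )
        t_hat = t_full.copy()
        t_hat[free_idx] = res.x
        params = replace(start, **_from_transformed(t_hat), seed=seed)

        bse = {name: float("nan") for name in _PARAM_NAMES}
        if compute_bse and res.success:
            try:
                cov_t = self._cov_transformed(negll, res.x)
                jac = _jacobian_natural(t_hat)[free_idx]
                se_nat = np.sqrt(np.maximum(np.diag(cov_t), 0.0)) * np.abs(jac)
                for i, idx in enumerate(free_idx):
                    bse[_PARAM_NAMES[idx]] = float(se_nat[i])
            except np.linalg.LinAlgError:
                pass
        return ObserverFitResults(
            model=self,
            params=params,
            bse=bse,
            llf=float(-res.fun),
            converged=bool(res.success),
            nfev=nfev,
            free=[_PARAM_NAMES[i] for i in free_idx],
            message=str(res.message),
        )

    @staticmethod
    def _cov_transformed(negll, x_hat, h: float = 1e-3):
        """Inverse finite-difference Hessian of the negative log-likelihood."""
        k = x_hat.size
        H = np.empty((k, k))
        f0 = negll(x_hat)
        steps = np.full(k, h)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = steps[i]
            H[i, i] = (negll(x_hat + ei) - 2 * f0 + negll(x_hat - ei)) / steps[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = steps[i]
                ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    negll(x_hat + ei + ej)
                    - negll(x_hat + ei - ej)
                    - negll(x_hat - ei + ej)
                    + negll(x_hat - ei - ej)
                ) / (4 * steps[i] * steps[j])
        return np.linalg.inv(H)


@dataclass
class ObserverFitResults:
    """Estimates, uncertainties and diagnostics from :meth:`ObserverModel.fit`."""

    model: ObserverModel
    params: ObserverParams
    bse: dict
    llf: float
    converged: bool
    nfev: int
    free: list
    message: str = ""

    def params_dict(self) -> dict:
        return {name: getattr(self.params, name) for name in _PARAM_NAMES}

    def simulate(self, design: pd.DataFrame) -> pd.DataFrame:
        """Simulate responses for a design from the fitted parameters."""
        return simulate_responses(design, self.params)

    def summary(self) -> str:
        lines = [
            "Resource-limited observer fit",
            "=" * 46,
            f"{'n trials':<22}{self.nobs_str():>24}",
            f"{'log-likelihood':<22}{self.llf:>24.2f}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'function evals':<22}{self.nfev:>24d}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}{'fitted':>10}",
            "-" * 46,
        ]
        for name in _PARAM_NAMES:
            est = getattr(self.params, name)
            se = self.bse.get(name, float("nan"))
            fitted = "yes" if name in self.free else "fixed"
            lines.append(f"{name:<12}{est:>12.4f}{se:>12.4f}{fitted:>10}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def nobs_str(self) -> str:
        return str(self.model.nobs)


def fit_observer(trials: pd.DataFrame, seed: int = 0, **kwargs) -> ObserverFitResults:
    """Fit the generative observer to a trial table (module-level helper).

    Thin wrapper over ``ObserverModel(trials).fit(...)``.
    """
    model_kw = {
        k: kwargs.pop(k) for k in ("n_latent", "n_response_grid") if k in kwargs
    }
    return ObserverModel(trials, **model_kw).fit(seed=seed, **kwargs)
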