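"""Bias correction of predicted age gaps by median regression.

Age regressors trained toward the cohort mean systematically overestimate
young and underestimate old subjects (regression to the mean).  Rather than
regressing the gap on chronological age alone - which would also strip out
variance carried by sex or disease status - the median of the raw predicted
age gap is modelled on chronological age *and* the covariates whose
influence should be preserved:

    Median(PAG_i | X_i) = beta0 + beta1' X_i,
    X_i = (CA_i, sex_i, existing_i, future_i)

and only the linear chronological-age effect is subtracted, anchored at the
cohort median age A_ref:

    pred_corr_i = pred_i - beta1_age * (CA_i - A_ref).

Median (tau = 0.5 quantile) regression is solved as an exact linear
program, which is deterministic and robust to outlying predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .config import DataError

COVARIATE_ORDER = ("ca", "sex", "existing", "future")


def pinball_loss(residuals, tau: float = 0.5) -> float:
    """Mean quantile (pinball) loss: tau*max(r,0) + (1-tau)*max(-r,0)."""
    r = np.asarray(list(residuals), dtype=np.float64)
    if r.size == 0:
        raise DataError("residual list must be nonempty")
    return float(np.mean(tau * np.maximum(r, 0.0) + (1.0 - tau) * np.maximum(-r, 0.0)))


def _quantile_lp(x: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact quantile regression via the standard LP formulation.

    minimize  (1/n) [tau * 1'u + (1-tau) * 1'v]
    s.t.      X beta + u - v = y,  u, v >= 0,  beta free.
    """
    n, p = x.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau / n), np.full(n, (1 - tau) / n)])
    a_eq = sparse.hstack([sparse.csr_matrix(x), sparse.eye(n), -sparse.eye(n)],
                         format="csr")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is reliable on these LPs
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    return res.x[:p]


@dataclass
class BiasFit:
    """Fitted median-regression bias model for one organ."""

    beta0: float
    beta1: dict[str, float]
    a_ref: float
    tau: float = 0.5
    n_obs: int = 0
    covariates: tuple[str, ...] = field(default=COVARIATE_ORDER)

    @property
    def beta1_age(self) -> float:
        return self.beta1["ca"]

    def correct(self, pred_age, ca) -> np.ndarray:
        """Remove the linear CA effect: pred - beta1_age * (CA - A_ref)."""
        pred_age = np.asarray(pred_age, dtype=np.float64)
        ca = np.asarray(ca, dtype=np.float64)
        return pred_age - self.beta1_age * (ca - self.a_ref)

    def summary(self) -> str:
        rows = [f"Median regression of the predicted age gap (tau={self.tau})",
                f"  n = {self.n_obs}, reference age = {self.a_ref:.2f} y",
                f"  intercept      {self.beta0:+.4f}"]
        units = {"ca": "per year", "sex": "years", "existing": "years",
                 "future": "years"}
        for name in self.covariates:
            rows.append(f"  {name:<14} {self.beta1[name]:+.4f} "
                        f"({units.get(name, '')})")
        return "\n".join(rows)

    def to_json(self, path) -> None:
        doc = {"beta0": self.beta0, "beta1": self.beta1, "a_ref": self.a_ref,
               "tau": self.tau, "n_obs": self.n_obs,
               "covariates": list(self.covariates)}
        Path(path).write_text(json.dumps(doc, indent=1))

    @staticmethod
    def from_json(path) -> "BiasFit":
        doc = json.loads(Path(path).read_text())
        return BiasFit(beta0=doc["beta0"], beta1=doc["beta1"],
                       a_ref=doc["a_ref"], tau=doc["tau"],
                       n_obs=doc.get("n_obs", 0),
                       covariates=tuple(doc["covariates"]))


class PagBiasModel:
    """Median-regression model of raw PAGs on CA and preserved covariates.

    Parameters
    ----------
    pag : raw predicted age gaps (predicted age minus CA), years.
    ca : chronological age at imaging, years.
    covariates : DataFrame with 0/1 columns ``sex`` (1 = male),
        ``existing`` and ``future`` pathology indicators.  May be None for a
        CA-only model.
    """

    def __init__(self, pag, ca, covariates: pd.DataFrame | None = None,
                 tau: float = 0.5):
        self.pag = np.asarray(pag, dtype=np.float64)
        self.ca = np.asarray(ca, dtype=np.float64)
        self.tau = float(tau)
        if covariates is None:
            covariates = pd.DataFrame(index=range(self.pag.size))
        self.covariates = covariates.reset_index(drop=True)
        names = ["ca"] + [c for c in COVARIATE_ORDER[1:] if c in covariates.columns]
        extra = [c for c in covariates.columns if c not in names]
        self.names: tuple[str, ...] = tuple(names + extra)
        n = self.pag.size
        if self.ca.size != n or len(self.covariates) != n:
            raise DataError("pag, ca and covariates must be aligned")
        if n <= len(self.names) + 1:
            raise DataError("need more observations than coefficients")
        for c in self.names[1:]:
            vals = np.unique(self.covariates[c].to_numpy())
            if not np.all(np.isin(vals, (0, 1))):
                raise DataError(f"covariate {c!r} must be a 0/1 indicator")

    def _design(self) -> np.ndarray:
        cols = [np.ones_like(self.ca), self.ca]
        for c in self.names[1:]:
            cols.append(self.covariates[c].to_numpy(dtype=np.float64))
        return np.column_stack(cols)

    def fit(self) -> BiasFit:
        x = self._design()
        if np.linalg.matrix_rank(x) < x.shape[1]:
            # name the columns involved in the collinearity via the QR diagonal
            labels = ("intercept",) + self.names
            diag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
            bad = [labels[i] for i in range(x.shape[1])
                   if diag[i] < 1e-8 * diag.max()]
            raise DataError(
                "rank-deficient design: collinear columns involve "
                f"{bad or list(labels)}")
        beta = _quantile_lp(x, self.pag, self.tau)
        return BiasFit(beta0=float(beta[0]),
                       beta1={name: float(b) for name, b in zip(self.names, beta[1:])},
                       a_ref=float(np.median(self.ca)), tau=self.tau,
                       n_obs=self.pag.size, covariates=self.names)


def fit_bias_model(pag, ca, covariates: pd.DataFrame | None = None,
                   tau: float = 0.5) -> BiasFit:
    """Functional wrapper around :class:`PagBiasModel`."""
    return PagBiasModel(pag, ca, covariates, tau=tau).fit()


def correct_predictions(pred_age, ca, model: BiasFit) -> np.ndarray:
    """Apply a fitted bias model to predicted ages (years in, years out)."""
    return model.correct(pred_age, ca)
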