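"""Model/Results interface over the six estimators.

``BinaryIVMR`` is constructed from per-subject data (arrays or a DataFrame)
and its :meth:`~BinaryIVMR.fit` returns a :class:`BinaryIVMRResults` carrying
every estimate, the 3x3 bias matrix between instrumental-variable and
Wald-ratio estimators, stage-level coefficients with standard errors, and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est

__all__ = ["BinaryIVMR", "BinaryIVMRResults"]


class BinaryIVMR:
    """Mendelian-randomization model with one binary instrument.

    Parameters
    ----------
    outcome, exposure, instrument : array-like of {0, 1}
        Per-subject binary outcome Y, exposure X and instrument Z.
    covariates : mapping or DataFrame, optional
        Named covariate columns entered into every regression stage of every
        estimator (both Wald stages and both IV stages).

    Examples
    --------
    >>> model = BinaryIVMR.from_dataframe(df, outcome="cancer",
    ...                                   exposure="activity", instrument="snp1",
    ...                                   covariates=["sex"])
    >>> res = model.fit()
    >>> res.estimates          # doctest: +SKIP
    """

    def __init__(self, outcome, exposure, instrument, covariates=None):
        self.outcome = np.asarray(outcome, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        self.instrument = np.asarray(instrument, dtype=float)
        if covariates is None:
            self.covariates = None
        elif hasattr(covariates, "columns"):
            self.covariates = {str(c): np.asarray(covariates[c], dtype=float)
                               for c in covariates.columns}
        else:
            self.covariates = {str(k): np.asarray(v, dtype=float)
                               for k, v in covariates.items()}
        n = self.outcome.shape[0]
        if self.exposure.shape[0] != n or self.instrument.shape[0] != n:
            raise ValueError("outcome, exposure, instrument must share length")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "Y",
        exposure: str = "X",
        instrument: str = "Z",
        covariates: Optional[Sequence[str]] = None,
        dropna: bool = True,
    ) -> "BinaryIVMR":
        """Build the model from named columns of a DataFrame.

        ``dropna`` restricts to complete cases over the used columns.
        """
        cols = [outcome, exposure, instrument] + list(covariates or [])
        sub = data[cols]
        if dropna:
            sub = sub.dropna()
        return cls(
            outcome=sub[outcome],
            exposure=sub[exposure],
            instrument=sub[instrument],
            covariates=sub[list(covariates)] if covariates else None,
        )

    def fit(self) -> "BinaryIVMRResults":
        fitted = est.estimate_all(
            (self.instrument, self.exposure, self.outcome), self.covariates
        )
        return BinaryIVMRResults(self, fitted)


class BinaryIVMRResults:
    """Estimates, diagnostics and summary for a fitted :class:`BinaryIVMR`."""

    def __init__(self, model: BinaryIVMR, fitted: est.MREstimates):
        self.model = model
        self._fitted = fitted
        self.wald = fitted.wald
        self.iv = fitted.iv
        self.nobs = fitted.n
        self.prevalence_x = fitted.pr_x
        self.prevalence_y = fitted.pr_y

    @property
    def estimates(self) -> pd.Series:
        """All six point estimates on the log-odds scale (NaN if invalid)."""
        vals = {}
        for name, e in {**self.iv, **self.wald}.items():
            key = name if name in self.iv else f"wald_{name}"
            vals[key] = e.estimate if e.valid else np.nan
        return pd.Series(vals, name="log_odds")

    def bias_matrix(self) -> pd.DataFrame:
        """IV estimate minus Wald estimate for the nine estimator pairs."""
        from .bias_study import IV_METHODS, WALD_METHODS

        bias, _ = self._fitted.bias_matrix()
        return pd.DataFrame(bias, index=list(IV_METHODS), columns=list(WALD_METHODS))

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-estimator table (serializes to CSV unchanged)."""
        rows = []
        for name, e in self.wald.items():
            rows.append(dict(method=f"wald_{name}", estimate=e.estimate,
                             valid=e.valid, numerator=e.numerator,
                             denominator=e.denominator, pr_x=e.pr_x, pr_y=e.pr_y,
                             residual_coefficient=np.nan))
        for name, e in self.iv.items():
            rows.append(dict(method=name, estimate=e.estimate, valid=e.valid,
                             numerator=np.nan, denominator=np.nan,
                             pr_x=np.nan, pr_y=np.nan,
                             residual_coefficient=(
                                 e.residual_coefficient
                                 if e.residual_coefficient is not None else np.nan)))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of all estimators on this dataset."""
        lines = [
            "Binary-instrument Mendelian randomization",
            "=" * 57,
            f"n = {self.nobs}    P(X=1) = {self.prevalence_x:.3f}    "
            f"P(Y=1) = {self.prevalence_y:.3f}",
            "-" * 57,
            f"{'method':<22}{'estimate':>12}{'valid':>8}",
            "-" * 57,
        ]
        order = [("wald_logistic", self.wald["logistic"]),
                 ("wald_lpm", self.wald["lpm"]),
                 ("wald_transformation", self.wald["transformation"]),
                 ("sem", self.iv["sem"]),
                 ("tsps", self.iv["tsps"]),
                 ("tsri", self.iv["tsri"])]
        for name, e in order:
            val = f"{e.estimate:.4f}" if e.valid else "--"
            lines.append(f"{name:<22}{val:>12}{str(e.valid):>8}")
        lines.append("-" * 57)
        lines.append("estimates on the log-odds scale; IV minus Wald differences")
        lines.append("available via .bias_matrix()")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<BinaryIVMRResults n={self.nobs}>"
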