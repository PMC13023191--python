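"""Applied Mendelian-randomization workflow on a subject-level cohort table.

Covers the steps of a single-cohort MR analysis with binary-coded SNPs:
reading a flat CSV (or a PLINK ``--recode A`` ``.raw`` export), screening
each SNP for association with the exposure (chi-square, or Fisher's exact
test when expected cell counts are small), then running the confounder-
adjusted SEM/TSPS/TSRI estimators and the three Wald ratios per SNP on
complete cases, with the IV-minus-Wald bias matrix.

A fixture generator (:func:`make_fixture`) emulates the structure of a
dog-cohort cancer study: one binary outcome (cancer), one binary exposure
(activity level), several binary SNP instruments and four binary
confounders, with intercepts calibrated by root finding so the realized
prevalences hit requested targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .estimators import EstimationError, estimate_all
from .bias_study import IV_METHODS, WALD_METHODS

__all__ = [
    "SubjectTable",
    "AssociationResult",
    "Table5Row",
    "FixtureProfile",
    "ValidationError",
    "CalibrationError",
    "DegenerateTableError",
    "read_subject_table",
    "read_plink_raw",
    "snp_screen",
    "rank_snps",
    "select_snps",
    "analyze_snp",
    "make_fixture",
]


class ValidationError(ValueError):
    """A coded column contains values other than 0, 1 or missing."""


class CalibrationError(RuntimeError):
    """An intercept satisfying the prevalence target does not exist."""


class DegenerateTableError(ValueError):
    """A 2x2 association table has a zero margin."""


# ---------------------------------------------------------------------------
# subject table

@dataclass
class SubjectTable:
    """A validated cohort table with role-tagged columns.

    ``data`` holds one row per subject; instrument/exposure/outcome/confounder
    columns are {0, 1} with NaN allowed per cell. Rows missing the exposure or
    outcome are retained but excluded from every complete-case analysis.
    """

    data: pd.DataFrame
    instruments: list[str]
    exposure: str
    outcome: str
    confounders: list[str] = field(default_factory=list)
    id_col: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.data)

    def coded_columns(self) -> list[str]:
        return self.instruments + [self.exposure, self.outcome] + self.confounders

    def incomplete_phenotype_rows(self) -> np.ndarray:
        """Indices of rows with a missing exposure or outcome."""
        mask = self.data[[self.exposure, self.outcome]].isna().any(axis=1)
        return np.flatnonzero(mask.to_numpy())

    def complete_mask(self, snp: str) -> np.ndarray:
        """Boolean mask of complete cases for one SNP's analysis."""
        cols = [snp, self.exposure, self.outcome] + self.confounders
        return ~self.data[cols].isna().any(axis=1).to_numpy()

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _validate_coded(df: pd.DataFrame, columns: Sequence[str]) -> None:
    problems = []
    for col in columns:
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1])
        if bad.any():
            rows = [int(r) for r in df.index[bad][:10]]
            problems.append(f"column {col!r}: non-binary values at rows {rows}")
    if problems:
        raise ValidationError("; ".join(problems))


def read_subject_table(path, column_map: dict) -> SubjectTable:
    """Read and validate a flat CSV cohort table.

    ``column_map`` maps roles to column names: ``instruments`` (list),
    ``exposure``, ``outcome``, optional ``confounders`` (list) and ``id``.
    """
    df = pd.read_csv(path)
    instruments = list(column_map.get("instruments", []))
    if not instruments:
        raise KeyError("column_map must name at least one instrument column")
    exposure = column_map["exposure"]
    outcome = column_map["outcome"]
    confounders = list(column_map.get("confounders", []))
    id_col = column_map.get("id")
    required = instruments + [exposure, outcome] + confounders
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"mapped columns absent from file: {missing}")
    _validate_coded(df, required)
    return SubjectTable(
        data=df, instruments=instruments, exposure=exposure,
        outcome=outcome, confounders=confounders, id_col=id_col,
    )


# ---------------------------------------------------------------------------
# PLINK .raw genotypes

_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")

#: additive dosage -> binary instrument coding rules
_CODINGS = {
    "carrier": lambda d: (d >= 1).astype(float),    # any effect allele
    "dominant": lambda d: (d >= 1).astype(float),   # alias of carrier
    "recessive": lambda d: (d == 2).astype(float),  # homozygous effect allele
    "major": lambda d: (d <= 1).astype(float),      # carries the major allele
}


def read_plink_raw(path, coding: str = "carrier") -> pd.DataFrame:
    """Parse a PLINK ``--recode A`` ``.raw`` export into binary instruments.

    Additive dosages {0, 1, 2, NA} are mapped to {0, 1, NaN} by ``coding``
    (default carrier: dosage >= 1 -> 1). Returns a frame with ``IID`` plus one
    binary column per SNP, names preserved.
    """
    if coding not in _CODINGS:
        raise ValueError(f"unknown coding {coding!r}; expected one of {sorted(_CODINGS)}")
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    header = list(df.columns[: len(_RAW_META)])
    if header != list(_RAW_META):
        raise ValueError(
            f"malformed .raw header: expected leading columns {_RAW_META}, got {header}"
        )
    snps = list(df.columns[len(_RAW_META):])
    out = pd.DataFrame({"IID": df["IID"]})
    rule = _CODINGS[coding]
    for snp in snps:
        dos = df[snp].astype(float)
        bad = dos.notna() & ~dos.isin([0.0, 1.0, 2.0])
        if bad.any():
            raise ValidationError(f"SNP {snp!r}: dosages outside {{0,1,2,NA}}")
        col = rule(dos)
        col[dos.isna()] = np.nan
        out[snp] = col
    return out


# ---------------------------------------------------------------------------
# association screen

@dataclass
class AssociationResult:
    snp: str
    test: str                 # "chi-square" | "fisher"
    statistic: Optional[float]
    p_value: float
    table: np.ndarray         # 2x2 counts, instrument rows x exposure columns


def snp_screen(table: SubjectTable, snp: str) -> AssociationResult:
    """Test association of one binary SNP with the exposure on a 2x2 table.

    Uses the Pearson chi-square test when every expected cell count is at
    least 5 (the conventional validity rule), otherwise the two-sided
    Fisher's exact test. Complete cases for (snp, exposure) only.
    """
    sub = table.data[[snp, table.exposure]].dropna()
    counts = pd.crosstab(sub[snp], sub[table.exposure])
    counts = counts.reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    obs = counts.to_numpy()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"SNP {snp!r}: a margin of the 2x2 table is zero"
        )
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected >= 5).all():
        stat, p, *_ = stats.chi2_contingency(obs, correction=False)
        return AssociationResult(snp, "chi-square", float(stat), float(p), obs)
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return AssociationResult(snp, "fisher", None, float(p), obs)


def rank_snps(table: SubjectTable) -> pd.DataFrame:
    """Screen every instrument column; one row per SNP sorted by p-value."""
    rows = []
    for snp in table.instruments:
        try:
            res = snp_screen(table, snp)
            rows.append(dict(snp=snp, test=res.test, statistic=res.statistic,
                             p_value=res.p_value))
        except DegenerateTableError:
            rows.append(dict(snp=snp, test="degenerate", statistic=np.nan,
                             p_value=np.nan))
    return (pd.DataFrame(rows)
            .sort_values("p_value", kind="mergesort", na_position="last")
            .reset_index(drop=True))


def select_snps(
    table: SubjectTable, choose: int = 5, top: int = 10,
    seed: Optional[int] = None,
) -> list[str]:
    """Pick SNPs for estimation from the screening ranking.

    Deterministic by default: the ``choose`` smallest p-values. With a seed,
    samples ``choose`` SNPs uniformly from the ``top`` smallest p-values.
    """
    ranked = rank_snps(table)
    ranked = ranked[ranked["p_value"].notna()]
    if seed is None:
        return ranked["snp"].head(choose).tolist()
    pool = ranked["snp"].head(top).tolist()
    rng = np.random.default_rng(seed)
    return list(rng.choice(pool, size=min(choose, len(pool)), replace=False))


# ---------------------------------------------------------------------------
# per-SNP estimation

@dataclass
class Table5Row:
    """All estimates and biases for one SNP on complete cases."""

    snp: str
    n_used: int
    prevalence_x: float
    prevalence_y: float
    causal: dict               # iv method -> CausalEstimate
    wald: dict                 # wald method -> WaldEstimate
    bias: pd.DataFrame         # 3x3, rows IV methods x columns Wald methods
    exposure_panel: pd.DataFrame  # SEM exposure-equation coefficients (95% CI)
    outcome_panel: pd.DataFrame   # SEM outcome-equation coefficients (95% CI)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ivm in IV_METHODS:
            e = self.causal[ivm]
            row = dict(snp=self.snp, method=ivm.upper(),
                       causal_effect=e.estimate if e.valid else np.nan)
            for wm in WALD_METHODS:
                w = self.wald[wm]
                row[f"wald_{wm}"] = w.estimate if w.valid else np.nan
                row[f"bias_{wm}"] = self.bias.loc[ivm, wm]
            rows.append(row)
        return pd.DataFrame(rows)


def _ci_panel(fit, drop: Sequence[str] = ("const",)) -> pd.DataFrame:
    if fit is None:
        return pd.DataFrame(columns=["coef", "se", "ci_low", "ci_high"])
    rows = {}
    for name, b, s in zip(fit.names, fit.coefficients, fit.standard_errors):
        if name in drop:
            continue
        rows[name] = dict(coef=float(b), se=float(s),
                          ci_low=float(b - 1.96 * s), ci_high=float(b + 1.96 * s))
    return pd.DataFrame.from_dict(rows, orient="index")


def analyze_snp(
    table: SubjectTable, snp: str, confounders: Optional[Sequence[str]] = None
) -> Table5Row:
    """Run all six confounder-adjusted estimators for one SNP.

    Complete cases over (snp, exposure, outcome, confounders); estimator
    failures are reported per cell via validity flags and never abort the
    other cells. The coefficient panels come from the SEM pair of logistic
    fits (exposure on instrument + confounders; outcome on exposure +
    confounders), on the log-odds scale with 95% CIs.
    """
    confounders = list(table.confounders if confounders is None else confounders)
    mask = table.complete_mask(snp) if confounders == table.confounders else (
        ~table.data[[snp, table.exposure, table.outcome] + confounders]
        .isna().any(axis=1).to_numpy()
    )
    sub = table.data.loc[mask]
    Z = sub[snp].to_numpy(dtype=float)
    X = sub[table.exposure].to_numpy(dtype=float)
    Y = sub[table.outcome].to_numpy(dtype=float)
    cov = {c: sub[c].to_numpy(dtype=float) for c in confounders} or None

    fitted = estimate_all((Z, X, Y), cov)
    bias, _ = fitted.bias_matrix()
    sem = fitted.iv["sem"]
    return Table5Row(
        snp=snp,
        n_used=int(mask.sum()),
        prevalence_x=fitted.pr_x,
        prevalence_y=fitted.pr_y,
        causal=fitted.iv,
        wald=fitted.wald,
        bias=pd.DataFrame(bias, index=list(IV_METHODS), columns=list(WALD_METHODS)),
        exposure_panel=_ci_panel(sem.first_stage),
        outcome_panel=_ci_panel(sem.second_stage),
    )


# ---------------------------------------------------------------------------
# fixture generator

@dataclass(frozen=True)
class FixtureProfile:
    """Targets and effects for the synthetic cohort.

    Defaults emulate a dog-cohort cancer study: ~2340 subjects, exposure
    (high activity) prevalence 0.18, outcome (cancer) prevalence 0.091, five
    binary SNP instruments with log-odds effects near 0.7 on the exposure,
    and four binary confounders entering both logistic equations. Intercepts
    are calibrated, not specified.
    """

    n: int = 2340
    snp_names: tuple[str, ...] = ("SNP_1", "SNP_2", "SNP_3", "SNP_4", "SNP_5")
    snp_freq: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    snp_effects: tuple[float, ...] = (0.67, 0.64, 0.67, 0.67, 0.69)
    confounder_names: tuple[str, ...] = (
        "sex", "treated_insects", "treated_fertilizer", "treated_weeds")
    confounder_freq: tuple[float, ...] = (0.5, 0.5, 0.4, 0.3)
    conf_x_effects: tuple[float, ...] = (-0.26, -0.11, -0.64, -0.22)
    conf_y_effects: tuple[float, ...] = (-0.19, 0.07, 0.84, 0.40)
    beta1: float = 0.09
    latent_cx: float = 0.01
    latent_cy: float = 0.01
    target_px: float = 0.18
    target_py: float = 0.091
    snp_missing_rate: float = 0.003


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Root of mean(expit(b + eta)) = target over b in [-30, 30]."""
    def g(b):
        return float(expit(b + eta).mean()) - target

    lo, hi = -30.0, 30.0
    if g(lo) > 0 or g(hi) < 0:
        raise CalibrationError(
            f"prevalence target {target} unattainable for the given effects"
        )
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def make_fixture(profile: Optional[FixtureProfile] = None, seed: int = 0) -> SubjectTable:
    """Generate a synthetic cohort table from the simulator's model extended
    with binary confounders; deterministic given ``seed``."""
    p = profile or FixtureProfile()
    rng = np.random.default_rng(seed)
    n = p.n

    snps = {name: (rng.random(n) < f).astype(float)
            for name, f in zip(p.snp_names, p.snp_freq)}
    confs = {name: (rng.random(n) < f).astype(float)
             for name, f in zip(p.confounder_names, p.confounder_freq)}
    U = rng.standard_normal(n)

    eta_x = sum(e * snps[name] for name, e in zip(p.snp_names, p.snp_effects))
    eta_x = eta_x + sum(e * confs[name]
                        for name, e in zip(p.confounder_names, p.conf_x_effects))
    eta_x = eta_x + p.latent_cx * U
    a0 = _calibrate_intercept(eta_x, p.target_px)
    X = (rng.random(n) < expit(a0 + eta_x)).astype(float)

    eta_y = p.beta1 * X
    eta_y = eta_y + sum(e * confs[name]
                        for name, e in zip(p.confounder_names, p.conf_y_effects))
    eta_y = eta_y + p.latent_cy * U
    b0 = _calibrate_intercept(eta_y, p.target_py)
    Y = (rng.random(n) < expit(b0 + eta_y)).astype(float)

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    for name, col in snps.items():
        if p.snp_missing_rate > 0:
            col = col.copy()
            col[rng.random(n) < p.snp_missing_rate] = np.nan
        df[name] = col
    df["activity"] = X
    df["cancer"] = Y
    for name, col in confs.items():
        df[name] = col
    return SubjectTable(
        data=df,
        instruments=list(p.snp_names),
        exposure="activity",
        outcome="cancer",
        confounders=list(p.confounder_names),
        id_col="id",
    )
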