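"""Scoring-function calibration and evaluation.

Retrains the linear weight vector against measured ddG values (ordinary
least squares on the six energy terms, no intercept, after removing
high-clash rows), and evaluates any set of score columns with Pearson
correlation (plus p-value), Kendall tau-b, and ROC AUC for discriminating
binding improvement.

No-intercept regression is a physical constraint: a null mutation has zero
term changes and must predict ddG = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .energy import EnergyBreakdown, ScoreWeights

TERM_COLUMNS = list(EnergyBreakdown.TERM_NAMES)

#: Inferred "true negative" outliers: correctly predicted non-binders whose
#: extreme scores would dominate a correlation. Overridable everywhere.
DEFAULT_OUTLIERS: tuple[tuple[str, str], ...] = (
    ("αG28I", "ELA"), ("αG28L", "ELA"), ("αG28N", "ELA"), ("αG28Y", "ELA"),
)

NO_BINDING = "NB"
FOLD_IMPROVEMENT_POSITIVE = 3.0     # measured fold change > 3 = positive
DDG_POSITIVE = -0.25                # alternative: measured ddG < -0.25 kcal/mol


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationDataset:
    """Rows of per-mutant energy terms / score columns with measurements.

    ``frame`` must carry columns ``mutant`` and ``ligand``; a ``ddg``
    column may contain the NO_BINDING flag ('NB'), in which case the row is
    usable only as a classification negative. Term columns (for weight
    fitting) are named after the six energy terms; arbitrary extra score
    columns (e.g. transcriptions of published score tables) are kept.
    """
    frame: pd.DataFrame

    def __post_init__(self):
        for col in ("mutant", "ligand"):
            if col not in self.frame.columns:
                raise CalibrationError(f"missing column {col!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationDataset":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged(cls, name: str = "table2.csv") -> "CalibrationDataset":
        """Load a fixture table shipped with the package."""
        text = resources.files("tcrdesign.data").joinpath(name).read_text()
        from io import StringIO
        return cls(pd.read_csv(StringIO(text)))

    def measured_ddg(self) -> pd.DataFrame:
        """Rows with a numeric measured ddG."""
        df = self.frame
        mask = df["ddg"].apply(lambda v: not (
            isinstance(v, str) and v.strip().upper() == NO_BINDING) and
            pd.notna(v))
        out = df[mask].copy()
        out["ddg"] = out["ddg"].astype(float)
        return out

    def term_matrix(self, clash_threshold: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """(X, y, excluded) for regression: six term columns vs measured ddG,
        optionally removing rows whose vdw_rep exceeds the clash threshold."""
        df = self.measured_ddg()
        missing = [c for c in TERM_COLUMNS if c not in df.columns]
        if missing:
            raise CalibrationError(f"dataset lacks term columns: {missing}")
        excluded = df.iloc[0:0]
        if clash_threshold is not None:
            clash = df["vdw_rep"] > clash_threshold
            excluded = df[clash]
            df = df[~clash]
        x = df[TERM_COLUMNS].to_numpy(dtype=float)
        y = df["ddg"].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise CalibrationError("non-finite term values")
        return x, y, excluded


def packaged_dmf5_dataset() -> CalibrationDataset:
    """The packaged DMF5 point-mutant dataset: score columns (ZF, Ros, ZFMin,
    RosMin) with measured ddG values, plus measured fold changes derived
    from the packaged affinity table (used to label AUC positives)."""
    from .thermo import derive_affinity_table

    ds = CalibrationDataset.packaged("table2.csv")
    text = resources.files("tcrdesign.data").joinpath("table1.csv").read_text()
    from io import StringIO
    derived = derive_affinity_table(pd.read_csv(StringIO(text)),
                                    ligand_ref="ELA")
    folds = {(r["mutant"], r["ligand"]): r["fold_change"]
             for _, r in derived.iterrows()}
    ds.frame["fold_change"] = [folds.get((m, l)) or 0.0
                               for m, l in zip(ds.frame["mutant"],
                                               ds.frame["ligand"])]
    return ds


def fit_weights(data: CalibrationDataset,
                clash_threshold: float = 580.0) -> ScoreWeights:
    """Ordinary least squares of measured ddG on the six terms, no intercept,
    after removing high-clash rows."""
    x, y, _ = data.term_matrix(clash_threshold=clash_threshold)
    if len(y) < 7:
        raise CalibrationError(
            f"need at least 7 usable rows to fit 6 weights, got {len(y)}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name (nearly) collinear columns via QR pivoting
        _, r = np.linalg.qr(x)
        bad = [TERM_COLUMNS[i] for i in range(x.shape[1])
               if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise CalibrationError(f"rank-deficient design; collinear terms: {bad}")
    w, *_ = np.linalg.lstsq(x, y, rcond=None)
    return ScoreWeights.from_array(w)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise CalibrationError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CalibrationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kendall_tau(x, y) -> float:
    """Kendall tau-b (tie-corrected) rank correlation."""
    tau, _ = stats.kendalltau(x, y)
    return float(tau)


def roc_auc(scores, labels) -> float:
    """ROC AUC where a lower (more negative) score ranks as more positive.

    Ties are handled by the Mann-Whitney convention (half credit).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise CalibrationError("ROC AUC needs both classes")
    return float(roc_auc_score(labels, -np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class EvaluationRow:
    function: str
    pearson_r: float
    p_value: float
    kendall: float
    auc: float
    n_correlation: int
    n_auc: int
    excluded: tuple[tuple[str, str], ...]


@dataclass
class EvaluationReport:
    rows: list[EvaluationRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "function": r.function, "pearson_r": r.pearson_r,
            "p_value": r.p_value, "kendall_tau": r.kendall, "roc_auc": r.auc,
            "n_correlation": r.n_correlation, "n_auc": r.n_auc,
            "excluded": ";".join(f"{m}/{l}" for m, l in r.excluded),
        } for r in self.rows])

    def row(self, function: str) -> EvaluationRow:
        for r in self.rows:
            if r.function == function:
                return r
        raise KeyError(function)


def evaluate_functions(data: CalibrationDataset,
                       functions: list[str] | dict[str, ScoreWeights],
                       outliers: tuple[tuple[str, str], ...] = DEFAULT_OUTLIERS,
                       positive_definition: str = "fold",
                       fold_column: str = "fold_change") -> EvaluationReport:
    """Correlation and ROC AUC summary per scoring function.

    ``functions`` is either a list of existing score columns, or a mapping
    of names to weight vectors applied to the six term columns. Correlations
    use the rows with measured ddG minus the explicit outlier exclusions;
    AUC uses every row, with positives defined by measured fold improvement
    > 3 (default) or measured ddG < -0.25 kcal/mol
    (``positive_definition="ddg"``).
    """
    df = data.frame.copy()
    if isinstance(functions, dict):
        for name, w in functions.items():
            df[name] = df[TERM_COLUMNS].to_numpy(dtype=float) @ w.as_array()
        names = list(functions)
    else:
        names = list(functions)
        for name in names:
            if name not in df.columns:
                raise CalibrationError(f"unknown score column {name!r}")

    measured = CalibrationDataset(df).measured_ddg()
    excl_mask = measured.apply(
        lambda r: (r["mutant"], r["ligand"]) in set(outliers), axis=1)
    corr_df = measured[~excl_mask]

    if positive_definition == "fold":
        if fold_column not in df.columns:
            raise CalibrationError(f"no column {fold_column!r} for positives")
        fold = pd.to_numeric(df[fold_column], errors="coerce").fillna(0.0)
        positives = fold > FOLD_IMPROVEMENT_POSITIVE
    elif positive_definition == "ddg":
        ddg = pd.to_numeric(df["ddg"], errors="coerce")
        positives = ddg < DDG_POSITIVE
        positives = positives.fillna(False)
    else:
        raise CalibrationError(f"unknown positive definition {positive_definition!r}")

    report = EvaluationReport()
    for name in names:
        r, p = pearson_with_p(corr_df[name], corr_df["ddg"])
        tau = kendall_tau(corr_df[name], corr_df["ddg"])
        auc = roc_auc(df[name], positives)
        report.rows.append(EvaluationRow(
            function=name, pearson_r=r, p_value=p, kendall=tau, auc=auc,
            n_correlation=len(corr_df), n_auc=len(df),
            excluded=tuple(outliers)))
    return report
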