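"""Clinical biomarkers, agreement analysis, and paired statistics.

The biomarkers are the inlet-outlet pressure drop PD (mmHg), the maximum
smoothed wall shear stress WSS_max (Pa), and the maximum velocity magnitude
V_max (m/s) in the stenosis region.  Agreement between predicted and
reference values is quantified with Bland-Altman statistics (mean
difference, SD with n-1 denominator, mean +/- 1.96 SD limits), treatment
decisions are classified against the guideline threshold of a 20 mmHg
peak-to-peak gradient (strictly greater), and paired comparisons use a
Shapiro-Wilk normality gate on the paired differences to choose between a
paired two-tailed t-test (normal; summarised mean +/- SD) and a Wilcoxon
signed-rank test (non-normal; summarised median [IQR]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError
from .nn.losses import masked_rmse

__all__ = [
    "BiomarkerSet",
    "AgreementReport",
    "ClassificationReport",
    "PairedTestResult",
    "pressure_drop",
    "extract_biomarkers",
    "pointwise_rmse",
    "bland_altman",
    "classify_treatment",
    "bernoulli_pd",
    "relative_change",
    "compare_paired",
    "EvalReport",
    "evaluate_predictions",
]

TREATMENT_THRESHOLD_MMHG = 20.0
"""Guideline peak-to-peak gradient above which intervention is recommended."""

STENOSIS_WINDOW_POINTS = 10
"""Half-width (in centerline points, i.e. +/-20 mm at 2 mm spacing) of the
stenosis region used for V_max."""


@dataclass(frozen=True)
class BiomarkerSet:
    """Per-case scalar biomarkers."""

    pd: float  # mmHg
    wss_max: float  # Pa
    v_max: float  # m/s

    def __post_init__(self):
        if not np.isfinite([self.pd, self.wss_max, self.v_max]).all():
            raise ParameterError("biomarkers must be finite")
        if self.wss_max < 0 or self.v_max < 0:
            raise ParameterError("WSS_max and V_max must be non-negative")


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement between predicted and reference values."""

    mean_error: float
    sd_error: float
    loa_lower: float
    loa_upper: float
    differences: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.differences)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts for the treatment-threshold decision."""

    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        # undefined (NaN) when the sample contains no positive cases
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a normality-gated paired comparison."""

    test: str  # "t-test", "wilcoxon", or "identical"
    statistic: float
    p_value: float
    normal: bool
    summary_a: str
    summary_b: str


def pressure_drop(p: np.ndarray, valid_length: int | None = None) -> float:
    """Inlet-minus-outlet pressure drop; padding beyond ``valid_length`` ignored.

    May be negative: a model is free to predict a higher outlet than inlet
    pressure.
    """
    p = np.asarray(p, dtype=float)
    n = len(p) if valid_length is None else int(valid_length)
    if n < 2 or n > len(p):
        raise ParameterError("valid_length must be in [2, len(p)]")
    return float(p[0] - p[n - 1])


def extract_biomarkers(
    pressure: np.ndarray,
    wss: np.ndarray,
    v_max: np.ndarray,
    radius: np.ndarray | None = None,
    valid_length: int | None = None,
    stenosis_window: int = STENOSIS_WINDOW_POINTS,
) -> BiomarkerSet:
    """PD, WSS_max and stenosis-region V_max from per-point channels.

    The stenosis region is ``+/- stenosis_window`` points around the radius
    argmin; without a radius profile the window covers the whole aorta.
    """
    n = len(pressure) if valid_length is None else int(valid_length)
    pd = pressure_drop(pressure, n)
    wss_max = float(np.max(np.asarray(wss, dtype=float)[:n]))
    v = np.asarray(v_max, dtype=float)[:n]
    if radius is not None:
        i_t = int(np.argmin(np.asarray(radius, dtype=float)[:n]))
        lo, hi = max(0, i_t - stenosis_window), min(n, i_t + stenosis_window + 1)
        v = v[lo:hi]
    return BiomarkerSet(pd=pd, wss_max=wss_max, v_max=float(np.max(v)))


def pointwise_rmse(
    p_pred: np.ndarray, p_ref: np.ndarray, valid_length: int | None = None
) -> float:
    """RMSE between two pressure curves over the valid points only.

    Delegates to the shared masked-RMSE kernel so the evaluation metric and
    the training loss are one and the same computation.
    """
    p_pred = np.asarray(p_pred, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if p_pred.shape != p_ref.shape:
        raise ParameterError("pressure curves must have equal length")
    n = len(p_pred) if valid_length is None else int(valid_length)
    mask = np.arange(len(p_pred)) < n
    return masked_rmse(p_pred, p_ref, mask)


def bland_altman(pred: np.ndarray, ref: np.ndarray) -> AgreementReport:
    """Bland-Altman agreement: differences are predicted minus reference."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ParameterError("pred and ref must be paired 1D arrays")
    if len(pred) < 2:
        raise ParameterError("Bland-Altman needs at least 2 paired cases")
    d = pred - ref
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        mean_error=mean,
        sd_error=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        differences=d,
    )


def classify_treatment(
    pd_pred: np.ndarray,
    pd_ref: np.ndarray,
    threshold: float = TREATMENT_THRESHOLD_MMHG,
) -> ClassificationReport:
    """Confusion counts of the intervention decision PD > threshold (strict)."""
    pd_pred = np.asarray(pd_pred, dtype=float)
    pd_ref = np.asarray(pd_ref, dtype=float)
    if pd_pred.shape != pd_ref.shape:
        raise ParameterError("predicted and reference PDs must be paired")
    pos_pred = pd_pred > threshold
    pos_ref = pd_ref > threshold
    return ClassificationReport(
        tp=int(np.sum(pos_pred & pos_ref)),
        tn=int(np.sum(~pos_pred & ~pos_ref)),
        fp=int(np.sum(pos_pred & ~pos_ref)),
        fn=int(np.sum(~pos_pred & pos_ref)),
        threshold=threshold,
    )


def bernoulli_pd(v: float | np.ndarray) -> float | np.ndarray:
    """Simplified clinical Bernoulli gradient PD = 4 * v^2 (v in m/s, PD in mmHg)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ParameterError("velocity must be non-negative")
    out = 4.0 * v**2
    return float(out) if out.ndim == 0 else out


def relative_change(value: float, reference: float) -> float:
    """Signed relative change (value - reference) / reference, as a percentage."""
    if reference == 0:
        raise ParameterError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


def _none_if_nan(value: float) -> float | None:
    return None if np.isnan(value) else value


@dataclass
class EvalReport:
    """Cohort-level evaluation of predicted vs reference output curves."""

    per_case: "object"  # pandas DataFrame: one row per case
    agreement: dict[str, AgreementReport]
    classification: ClassificationReport
    paired: dict[str, "PairedTestResult"]
    median_rmse: float

    def to_json(self) -> str:
        import json

        payload = {
            "median_rmse_mmHg": self.median_rmse,
            "classification": {
                "tp": self.classification.tp,
                "tn": self.classification.tn,
                "fp": self.classification.fp,
                "fn": self.classification.fn,
                "threshold_mmHg": self.classification.threshold,
                "sensitivity": _none_if_nan(self.classification.sensitivity),
                "specificity": _none_if_nan(self.classification.specificity),
            },
            "agreement": {
                name: {
                    "mean_error": r.mean_error,
                    "sd_error": r.sd_error,
                    "loa": [r.loa_lower, r.loa_upper],
                    "n": r.n,
                }
                for name, r in self.agreement.items()
            },
            "paired": {
                name: {
                    "test": t.test,
                    "statistic": None if np.isnan(t.statistic) else t.statistic,
                    "p_value": t.p_value,
                    "pred": t.summary_a,
                    "ref": t.summary_b,
                }
                for name, t in self.paired.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, out_dir) -> None:
        """Write the JSON summary and the per-case CSV."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "eval_report.json").write_text(self.to_json())
        self.per_case.to_csv(out_dir / "eval_per_case.csv", index=False)


def evaluate_predictions(
    pred: np.ndarray,
    ref: np.ndarray,
    valid_lengths: np.ndarray,
    radius: np.ndarray | None = None,
    threshold: float = TREATMENT_THRESHOLD_MMHG,
    stenosis_window: int = STENOSIS_WINDOW_POINTS,
    case_ids: list[str] | None = None,
) -> EvalReport:
    """Full cohort evaluation of padded (C, T, 8) output predictions.

    ``radius`` is the (C, T) radius feature used to locate the stenosis
    region for V_max.  Channels follow the canonical output order
    (pressure, wss, sfd, ke, tke_avg, tke_max, v_avg, v_max).
    """
    import pandas as pd

    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 3:
        raise ParameterError("pred and ref must be matching (C, T, 8) arrays")
    rows = []
    for c in range(len(pred)):
        n = int(valid_lengths[c])
        r = radius[c] if radius is not None else None
        bm_pred = extract_biomarkers(
            pred[c, :, 0], pred[c, :, 1], pred[c, :, 7], r, n, stenosis_window
        )
        bm_ref = extract_biomarkers(
            ref[c, :, 0], ref[c, :, 1], ref[c, :, 7], r, n, stenosis_window
        )
        rows.append(
            {
                "case_id": case_ids[c] if case_ids else str(c),
                "pd_pred": bm_pred.pd, "pd_ref": bm_ref.pd,
                "wss_max_pred": bm_pred.wss_max, "wss_max_ref": bm_ref.wss_max,
                "v_max_pred": bm_pred.v_max, "v_max_ref": bm_ref.v_max,
                "rmse_p": pointwise_rmse(pred[c, :, 0], ref[c, :, 0], n),
            }
        )
    table = pd.DataFrame(rows)
    agreement = {
        name: bland_altman(table[f"{name}_pred"].to_numpy(), table[f"{name}_ref"].to_numpy())
        for name in ("pd", "wss_max", "v_max")
    }
    classification = classify_treatment(
        table["pd_pred"].to_numpy(), table["pd_ref"].to_numpy(), threshold
    )
    paired = {}
    if len(table) >= 3:
        for name in ("pd", "wss_max", "v_max"):
            paired[name] = compare_paired(
                table[f"{name}_pred"].to_numpy(), table[f"{name}_ref"].to_numpy()
            )
    return EvalReport(
        per_case=table,
        agreement=agreement,
        classification=classification,
        paired=paired,
        median_rmse=float(table["rmse_p"].median()),
    )


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}–{q3:.2f}]"


def compare_paired(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> PairedTestResult:
    """Normality-gated paired comparison of two matched samples.

    A Shapiro-Wilk test on the paired differences decides the branch: if
    normality is not rejected at ``alpha``, a paired two-tailed t-test is
    run and both samples are summarised as mean +/- SD; otherwise a
    Wilcoxon signed-rank test is run with median [IQR] summaries.  Fully
    identical samples are reported without a test statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("samples must be paired 1D arrays")
    if len(a) < 3:
        raise ParameterError("paired comparison needs at least 3 cases")
    d = a - b
    if np.all(d == 0.0):
        return PairedTestResult(
            test="identical", statistic=np.nan, p_value=1.0, normal=True,
            summary_a=_summary(a, True), summary_b=_summary(b, True),
        )
    sw_p = stats.shapiro(d).pvalue
    normal = sw_p > alpha
    if normal:
        res = stats.ttest_rel(a, b)
        name = "t-test"
    else:
        res = stats.wilcoxon(a, b)
        name = "wilcoxon"
    return PairedTestResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normal=normal,
        summary_a=_summary(a, normal),
        summary_b=_summary(b, normal),
    )
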