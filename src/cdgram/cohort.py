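"""Reference-standard labeling and diagnostic-performance statistics.

A cohort row carries the CCTA stenosis category, the CT-FFR value, an
occlusion flag, the physician's ECG call and the CDG value.  Four composite
reference standards define CAD positivity as a stenosis cut (>= 50% or
>= 70%) OR a CT-FFR cut (<= 0.8 or <= 0.7); occluded vessels are assigned a
CT-FFR of 0.5 before comparison.

Diagnostic metrics (sensitivity, specificity, PPV, NPV, accuracy) are
reported as percentages rounded half-up to 2 decimals; undefined ratios
(zero denominators) are reported as missing, never as 0.  ROC AUC uses all
CDG-value thresholds (trapezoidal, equal to the normalized Mann-Whitney U
statistic) with a DeLong or stratified-bootstrap 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LabelingError, SchemaError, TrainingError

#: Ordered stenosis bands and their lower edges (percent).
STENOSIS_BANDS = ("0", "1-24", "25-49", "50-69", "70-99", "100")
_BAND_LOWER = {"0": 0, "1-24": 1, "25-49": 25, "50-69": 50, "70-99": 70, "100": 100}

#: The four composite reference standards: (stenosis cut %, CT-FFR cut).
REFERENCE_STANDARDS = {
    1: (50, 0.8),
    2: (50, 0.7),
    3: (70, 0.8),
    4: (70, 0.7),
}


@dataclass
class ReferenceStandard:
    stenosis_cut: int
    ctffr_cut: float

    def __post_init__(self):
        if self.stenosis_cut not in (50, 70) or self.ctffr_cut not in (0.7, 0.8):
            raise ValueError("unsupported reference standard cuts")

    @classmethod
    def by_number(cls, k: int) -> "ReferenceStandard":
        if k not in REFERENCE_STANDARDS:
            raise ValueError("reference standard must be 1..4")
        return cls(*REFERENCE_STANDARDS[k])


@dataclass
class CohortRecord:
    subject_id: str
    stenosis_band: str
    ctffr: float
    occluded: bool = False
    ecg_call: str | None = None
    cdg_value: float | None = None

    def __post_init__(self):
        self.stenosis_band = normalize_band(self.stenosis_band)
        if self.ctffr is not None and not (0.0 <= self.ctffr <= 1.0):
            raise SchemaError(f"CT-FFR {self.ctffr} outside [0, 1]")


def normalize_band(band) -> str:
    """Accept '25-49', '25–49', 70, '100' ... and return the canonical band."""
    s = str(band).strip().replace("−", "-").replace("–", "-")
    if s in _BAND_LOWER:
        return s
    try:
        v = float(s)
    except ValueError:
        raise SchemaError(f"unknown stenosis band {band!r}") from None
    for name in reversed(STENOSIS_BANDS):
        if v >= _BAND_LOWER[name]:
            return name
    raise SchemaError(f"unknown stenosis band {band!r}")


def label_cad(rec: CohortRecord, std: ReferenceStandard) -> str:
    """Composite positivity: stenosis >= cut OR CT-FFR <= cut.

    Occlusion forces CT-FFR to 0.5 before the comparison, so an occluded
    vessel is positive under every standard.
    """
    band = rec.stenosis_band
    ctffr = 0.5 if rec.occluded else rec.ctffr
    if band is None and ctffr is None:
        raise LabelingError(f"{rec.subject_id}: neither stenosis nor CT-FFR available")
    if band is not None and _BAND_LOWER[band] >= std.stenosis_cut:
        return "positive"
    if ctffr is not None and ctffr <= std.ctffr_cut:
        return "positive"
    return "negative"


# -- physician-style ischemia reading on measured ECG features --------------

#: Contiguous lead pairs for the two-adjacent-leads rules.
ADJACENT_PAIRS = (
    ("V1", "V2"), ("V2", "V3"), ("V3", "V4"), ("V4", "V5"), ("V5", "V6"),
    ("II", "III"), ("III", "aVF"), ("II", "aVF"),
    ("I", "aVL"), ("aVL", "V5"), ("V6", "I"),
)

_KNOWN_LEADS = {"I", "II", "III", "aVR", "aVL", "aVF",
                "V1", "V2", "V3", "V4", "V5", "V6"}


def ecg_ischemia_call(features: dict, sex: str = "male") -> str:
    """Apply the printed resting-ECG ischemia criteria to measured features.

    ``features`` maps lead name to a dict with keys (all optional, default 0):
    ``st_dev_mv`` (ST deviation, + elevation / - depression), ``st_slope``
    ("horizontal", "down" or "up"), ``t_amp_mv``, ``r_amp_mv``, ``s_amp_mv``.

    Positive if any criterion holds:

    1. ST elevation >= 0.2 mV (men) / 0.15 mV (women) in V2 or V3, or
       >= 0.1 mV in any other lead;
    2. horizontal or down-sloping ST depression >= 0.05 mV in two adjacent
       leads;
    3. T-wave inversion >= 0.1 mV in two adjacent leads with a prominent
       R wave or R/S > 1.
    """
    unknown = set(features) - _KNOWN_LEADS
    if unknown:
        raise ValueError(f"unknown lead names: {sorted(unknown)}")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    v23_cut = 0.2 if sex == "male" else 0.15

    def get(lead, key, default=0.0):
        return features.get(lead, {}).get(key, default)

    # criterion 1: ST elevation
    for lead in features:
        elev = get(lead, "st_dev_mv")
        cut = v23_cut if lead in ("V2", "V3") else 0.1
        if elev >= cut:
            return "positive"

    def depressed(lead):
        return (get(lead, "st_dev_mv") <= -0.05
                and get(lead, "st_slope", "horizontal") in ("horizontal", "down"))

    def inverted(lead):
        if get(lead, "t_amp_mv") > -0.1:
            return False
        r, s = get(lead, "r_amp_mv"), abs(get(lead, "s_amp_mv"))
        return r >= 0.5 or (s > 0 and r / s > 1)

    for a, b in ADJACENT_PAIRS:
        if a in features and b in features:
            if depressed(a) and depressed(b):
                return "positive"
            if inverted(a) and inverted(b):
                return "positive"
    return "negative"


# -- confusion counts and derived metrics -----------------------------------

@dataclass
class DiagnosticSummary:
    """Confusion counts and derived percentages for one reference standard."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    accuracy: float | None = None
    auc: float | None = None
    auc_ci: tuple | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "auc": self.auc,
        }
        if self.auc_ci is not None:
            d["auc_ci"] = list(self.auc_ci)
        return d


def _is_pos(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("positive", "pos", "+", "1", "true")
    return bool(v)


def confusion(calls, truths) -> tuple:
    """(tp, tn, fp, fn) from paired call/truth sequences."""
    if len(calls) != len(truths):
        raise SchemaError(f"{len(calls)} calls vs {len(truths)} truths")
    tp = tn = fp = fn = 0
    for c, t in zip(calls, truths):
        c, t = _is_pos(c), _is_pos(t)
        if c and t:
            tp += 1
        elif not c and not t:
            tn += 1
        elif c:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    frac = Decimal(100 * num) / Decimal(den)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics(tp: int, tn: int, fp: int, fn: int) -> DiagnosticSummary:
    """Derived percentages, half-up rounded to 2 decimals; AUC not included."""
    n = tp + tn + fp + fn
    if n <= 0:
        raise SchemaError("empty confusion table")
    return DiagnosticSummary(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
        accuracy=_pct(tp + tn, n),
    )


def roc_auc(scores, truths, ci: str = "delong", n_boot: int = 2000,
            seed: int = 0, alpha: float = 0.05) -> tuple:
    """Trapezoidal AUC over all thresholds with a 95% CI.

    Returns ``(auc, (lo, hi))``.  ``ci`` is ``"delong"`` (default) or
    ``"bootstrap"`` (stratified).  Raises on single-class input.
    """
    from sklearn.metrics import roc_auc_score

    y = np.array([1 if _is_pos(t) else 0 for t in truths])
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise TrainingError("ROC requires both classes present")
    auc = float(roc_auc_score(y, s))
    if ci == "delong":
        lo, hi = _delong_ci(s, y, auc, alpha)
    elif ci == "bootstrap":
        lo, hi = _bootstrap_ci(s, y, n_boot, seed, alpha)
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return auc, (lo, hi)


def _midranks(x):
    return stats.rankdata(x, method="average")


def _delong_ci(scores, y, auc, alpha):
    """DeLong variance of the AUC via placement values."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - _midranks(pos)) / n          # placements of positives
    v01 = 1.0 - (all_r[m:] - _midranks(neg)) / m    # placements of negatives
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(scores, y, n_boot, seed, alpha):
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    pos_i, neg_i = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    vals = []
    for _ in range(n_boot):
        bi = np.concatenate([
            rng.choice(pos_i, len(pos_i), replace=True),
            rng.choice(neg_i, len(neg_i), replace=True),
        ])
        vals.append(roc_auc_score(y[bi], scores[bi]))
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def spearman_corr(x, y) -> tuple:
    """Spearman rank correlation with average ranks for ties: (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise SchemaError("length mismatch")
    if len(x) < 3:
        raise SchemaError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None  # undefined for constant vectors
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# -- cohort-level evaluation -------------------------------------------------

COHORT_COLUMNS = ("subject_id", "stenosis_band", "ctffr", "occluded",
                  "ecg_call", "cdg_value")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stenosis_band": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    bad = []
    for i, row in df.iterrows():
        try:
            normalize_band(row["stenosis_band"])
            if not (0 <= float(row["ctffr"]) <= 1):
                raise SchemaError("ctffr out of range")
        except (SchemaError, ValueError) as exc:
            bad.append((i, str(exc)))
    if bad:
        raise SchemaError(f"invalid cohort rows: {bad[:10]}")
    return df


def evaluate_cohort(df: pd.DataFrame, standard: int = 1,
                    ci: str = "delong", seed: int = 0) -> dict:
    """Label by the chosen standard and summarize CDG performance.

    Returns a dict with confusion counts, metrics, AUC (None when the cohort
    is single-class) and Spearman rho between CDG value and CT-FFR.
    """
    std = ReferenceStandard.by_number(standard)
    truths, calls = [], []
    for _, row in df.iterrows():
        rec = CohortRecord(
            subject_id=str(row["subject_id"]),
            stenosis_band=row["stenosis_band"],
            ctffr=float(row["ctffr"]),
            occluded=bool(row["occluded"]),
        )
        truths.append(label_cad(rec, std))
        calls.append("positive" if float(row["cdg_value"]) >= 0 else "negative")
    tp, tn, fp, fn = confusion(calls, truths)
    summ = metrics(tp, tn, fp, fn)
    scores = df["cdg_value"].to_numpy(dtype=float)
    y = [t == "positive" for t in truths]
    if len(set(y)) == 2:
        summ.auc, summ.auc_ci = roc_auc(scores, y, ci=ci, seed=seed)
    rho, p = spearman_corr(scores, df["ctffr"].to_numpy(dtype=float))
    out = summ.to_dict()
    out.update({
        "standard": standard,
        "n": summ.n,
        "n_positive": sum(y),
        "spearman_rho": rho,
        "spearman_p": p,
    })
    return out
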