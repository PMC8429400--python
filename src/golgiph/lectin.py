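"""Lectin-microarray differential glycan fingerprints.

Spot intensities are aggregated spots -> replicate means -> condition
mean +/- SD per lectin.  Two conditions are compared by a per-lectin
subtracted fingerprint (difference of means, two-tailed t-test on replicate
means, signed fold change), and two such comparisons can be intersected to
find lectins that change significantly in both cell pairs and, among those,
the ones whose changes point the same way.

Statistical conventions (deliberate, documented):

* The t-test runs on replicate means, not raw spots, respecting the
  nesting of spots within arrays.
* No multiple-testing correction by default (raw p < alpha across the
  panel, which inflates the family-wise error rate over 43 lectins);
  Benjamini-Hochberg is available via ``correction="bh"``.
* The signed fold change is ``mean_A / mean_B`` for increases and
  ``-mean_B / mean_A`` for decreases, so magnitudes are always >= 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PANEL_SIZE",
    "LectinPanel",
    "Fingerprint",
    "SubtractedFingerprint",
    "CrossPairResult",
    "aggregate",
    "subtract",
    "intersect_pairs",
    "heatmap_order",
    "radar_export",
    "read_gpr",
    "default_panel",
]

DEFAULT_PANEL_SIZE = 43

SPOT_COLUMNS = ("condition", "replicate_id", "lectin", "spot_index", "intensity")


@dataclass(frozen=True)
class LectinPanel:
    """Fixed-order lectin panel with pass-through glycotope annotations."""

    names: tuple[str, ...]
    glycotopes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("lectin names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_panel(n: int = DEFAULT_PANEL_SIZE) -> LectinPanel:
    """A placeholder panel L01..Lnn for synthetic data and tests."""
    return LectinPanel(names=tuple(f"L{i + 1:02d}" for i in range(n)))


@dataclass
class Fingerprint:
    """Per-lectin condition mean +/- SD over replicates.

    ``table`` has columns lectin, mean, sd, n; ``replicate_means`` maps
    lectin -> the per-replicate means the statistics run on.
    """

    condition: str
    table: pd.DataFrame
    replicate_means: dict[str, np.ndarray]

    @property
    def lectins(self) -> tuple[str, ...]:
        return tuple(self.table["lectin"])


@dataclass
class SubtractedFingerprint:
    """Differential fingerprint A - B with per-lectin significance.

    ``table`` columns: lectin, mean_a, mean_b, delta, p_value, significant,
    signed_fold_change.
    """

    condition_a: str
    condition_b: str
    alpha: float
    table: pd.DataFrame

    @property
    def significant_lectins(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "lectin"])

    def delta_sign(self, lectin: str) -> int:
        row = self.table.loc[self.table["lectin"] == lectin]
        if row.empty:
            raise KeyError(lectin)
        return int(np.sign(row["delta"].iloc[0]))


@dataclass
class CrossPairResult:
    common_significant: tuple[str, ...]
    concordant: tuple[str, ...]
    fold_changes: pd.DataFrame  # lectin, fold_pair1, fold_pair2, delta signs


def _validate_spot_table(spot_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPOT_COLUMNS if c not in spot_table.columns]
    if missing:
        raise ValueError(f"spot table missing column(s): {missing}")
    if (spot_table["intensity"] < 0).any():
        raise ValueError("spot intensities must be non-negative")
    return spot_table


def aggregate(spot_table: pd.DataFrame, condition: str | None = None) -> dict[str, Fingerprint]:
    """Aggregate a spot table into per-condition fingerprints.

    Spot intensities are first averaged within each replicate, then the
    replicate means yield the condition mean, SD (ddof=1) and n (replicate
    count, reported per lectin, not assumed balanced).  Lectins absent from
    some replicate of a condition raise an error listing the gaps.
    """
    df = _validate_spot_table(spot_table)
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no rows for condition {condition!r}")

    out: dict[str, Fingerprint] = {}
    for cond, sub in df.groupby("condition", sort=False):
        lectins = list(dict.fromkeys(sub["lectin"]))  # first-seen order
        replicates = list(dict.fromkeys(sub["replicate_id"]))
        present = sub.groupby("replicate_id")["lectin"].apply(set)
        gaps = [
            (rep, sorted(set(lectins) - present[rep]))
            for rep in replicates
            if set(lectins) - present[rep]
        ]
        if gaps:
            raise ValueError(f"condition {cond!r} has replicate gaps: {gaps}")
        rep_means = (
            sub.groupby(["lectin", "replicate_id"], sort=False)["intensity"].mean().unstack()
        )
        rep_means = rep_means.loc[lectins]
        means = rep_means.mean(axis=1)
        n = rep_means.notna().sum(axis=1)
        sds = rep_means.std(axis=1, ddof=1)
        if (n < 2).any():
            bad = list(n[n < 2].index)
            raise ValueError(f"condition {cond!r}: fewer than 2 replicates for {bad}")
        out[cond] = Fingerprint(
            condition=str(cond),
            table=pd.DataFrame(
                {"lectin": lectins, "mean": means.values, "sd": sds.values, "n": n.values}
            ),
            replicate_means={
                lec: rep_means.loc[lec].dropna().to_numpy() for lec in lectins
            },
        )
    return out


def subtract(
    fp_a: Fingerprint,
    fp_b: Fingerprint,
    alpha: float = 0.05,
    welch: bool = False,
    correction: str | None = None,
) -> SubtractedFingerprint:
    """Per-lectin differential fingerprint ``A - B``.

    Student's pooled-variance t-test (two-tailed) on the replicate means;
    ``correction="bh"`` applies Benjamini-Hochberg before thresholding at
    ``alpha`` (off by default).  A zero denominator leaves the fold change
    NaN while the delta is still reported.
    """
    if fp_a.lectins != fp_b.lectins:
        raise ValueError("fingerprints are not aligned to the same panel")
    rows = []
    for lec in fp_a.lectins:
        a = fp_a.replicate_means[lec]
        b = fp_b.replicate_means[lec]
        mean_a, mean_b = float(a.mean()), float(b.mean())
        delta = mean_a - mean_b
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        if mean_a >= mean_b:
            fold = mean_a / mean_b if mean_b > 0 else np.nan
        else:
            fold = -mean_b / mean_a if mean_a > 0 else np.nan
        rows.append((lec, mean_a, mean_b, delta, p, fold))
    table = pd.DataFrame(
        rows, columns=["lectin", "mean_a", "mean_b", "delta", "p_value", "signed_fold_change"]
    )
    pvals = table["p_value"].to_numpy()
    if correction == "bh":
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, pvals[i] * m / rank)
            adj[i] = prev
        table["p_adjusted"] = adj
        table["significant"] = adj < alpha
    elif correction is None:
        table["significant"] = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    table = table[
        ["lectin", "mean_a", "mean_b", "delta", "p_value", "significant", "signed_fold_change"]
        + (["p_adjusted"] if correction == "bh" else [])
    ]
    return SubtractedFingerprint(
        condition_a=fp_a.condition, condition_b=fp_b.condition, alpha=alpha, table=table
    )


def intersect_pairs(
    sf_pair1: SubtractedFingerprint, sf_pair2: SubtractedFingerprint
) -> CrossPairResult:
    """Lectins significant in both pairs, and the sign-concordant subset.

    Concordance is operationalized as matching delta sign only; no
    magnitude-similarity criterion is applied.
    """
    panel1 = tuple(sf_pair1.table["lectin"])
    panel2 = tuple(sf_pair2.table["lectin"])
    if panel1 != panel2:
        raise ValueError("subtracted fingerprints use different panels")
    sig1 = sf_pair1.significant_lectins
    sig2 = sf_pair2.significant_lectins
    common = tuple(lec for lec in panel1 if lec in sig1 and lec in sig2)
    concordant = tuple(
        lec for lec in common if sf_pair1.delta_sign(lec) == sf_pair2.delta_sign(lec)
    )
    t1 = sf_pair1.table.set_index("lectin")
    t2 = sf_pair2.table.set_index("lectin")
    folds = pd.DataFrame(
        {
            "lectin": common,
            "fold_pair1": [t1.loc[lec, "signed_fold_change"] for lec in common],
            "fold_pair2": [t2.loc[lec, "signed_fold_change"] for lec in common],
            "sign_pair1": [int(np.sign(t1.loc[lec, "delta"])) for lec in common],
            "sign_pair2": [int(np.sign(t2.loc[lec, "delta"])) for lec in common],
        }
    )
    return CrossPairResult(common_significant=common, concordant=concordant, fold_changes=folds)


def heatmap_order(
    fingerprints: dict[str, Fingerprint], reference_condition: str
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Sort lectins by descending mean intensity in the reference condition.

    Ties preserve the original panel order (stable sort).  Returns the
    ordered lectin tuple and a lectin x condition matrix of means.
    """
    if reference_condition not in fingerprints:
        raise KeyError(f"reference condition {reference_condition!r} not present")
    ref = fingerprints[reference_condition]
    means = ref.table.set_index("lectin")["mean"]
    order = means.iloc[
        np.argsort(-means.to_numpy(), kind="stable")
    ].index.tolist()
    matrix = pd.DataFrame(
        {
            cond: fp.table.set_index("lectin")["mean"].reindex(order)
            for cond, fp in fingerprints.items()
        }
    )
    return tuple(order), matrix


def radar_export(sf: SubtractedFingerprint) -> pd.DataFrame:
    """Panel-ordered table for radar/bar plots with an explicit zero baseline."""
    out = sf.table[["lectin", "delta", "significant", "signed_fold_change"]].copy()
    out["baseline"] = 0.0
    return out


# ---------------------------------------------------------------------------
# minimal GenePix GPR dialect


def read_gpr(path_or_buffer, condition: str, replicate_id: str) -> pd.DataFrame:
    """Read a minimal GenePix results (GPR) file into a spot table.

    Understands the textual dialect: an ``ATF`` magic line, a counts line,
    quoted ``"key=value"`` header lines, then a tab-separated block whose
    header names the columns.  Only ``Name`` and the first ``F... Median``
    column are consumed; rows with empty names are dropped.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8", errors="replace") as fh:
            text = fh.read()
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        cols = [c.strip().strip('"') for c in line.split("\t")]
        if "Name" in cols and any("Median" in c for c in cols):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError("no column-header line with 'Name' and a Median column found")
    df = pd.read_csv(
        io.StringIO("\n".join(lines[header_idx:])), sep="\t", quotechar='"'
    )
    median_cols = [c for c in df.columns if "Median" in c and c.strip().startswith("F")]
    if not median_cols:
        raise ValueError("no foreground median intensity column found")
    out = df[["Name", median_cols[0]]].rename(
        columns={"Name": "lectin", median_cols[0]: "intensity"}
    )
    out = out[out["lectin"].notna()]
    out = out[out["lectin"].astype(str).str.strip() != ""]
    out = out.reset_index(drop=True)
    out.insert(0, "condition", condition)
    out.insert(1, "replicate_id", replicate_id)
    out["spot_index"] = out.groupby("lectin").cumcount()
    return out[list(SPOT_COLUMNS)]
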