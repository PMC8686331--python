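"""Per-patient mutation-blot composition and clinical association analyses.

A patient's MB composition is the proportion of each MB class among
their SBSs.  Patients are clustered on those proportion vectors with
K-means (K = 7 by default, or chosen by the elbow of the within-cluster
sum-of-squares curve).  Group differences use the two-sample t test for
two groups, one-way ANOVA for more, and the chi-square test for
categorical outcomes; rows with a missing required item are dropped
per-analysis.  Survival differences use the log-rank test; for per-gene
analyses patients are grouped by the MB class of their mutations in that
gene, by default entering every MB group they carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans

from .encoding import CANONICAL_TYPES, CanonicalSubstitution

logger = logging.getLogger(__name__)


@dataclass
class PatientClassing:
    """Per-patient K-means class (1-based), the K used, and the
    within-cluster dispersion curve behind the elbow choice."""

    classes: pd.Series
    chosen_k: int
    dispersion_curve: Optional[pd.Series] = None

    def class_names(self) -> list[str]:
        return [f"Class {k}" for k in range(1, self.chosen_k + 1)]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    group_sizes: dict
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mb_composition(labels_frame: pd.DataFrame, patient_level: bool = True
                   ) -> pd.DataFrame:
    """Per-patient MB proportions from a labeling frame.

    ``labels_frame`` needs columns ``sample_barcode`` and ``mb`` (as
    written by :meth:`MBLabeling.to_frame`).  Rows sum to 1; the total
    SBS count per patient is kept in the ``n_sbs`` attribute column
    (returned as ``df.attrs["n_sbs"]``).
    """
    if labels_frame.empty:
        raise ValueError("empty labeling")
    df = labels_frame[["sample_barcode", "mb"]].copy()
    if patient_level:
        df["sample_barcode"] = (
            df["sample_barcode"].str.split("-").str[:3].str.join("-")
        )
    counts = (
        df.groupby(["sample_barcode", "mb"]).size().unstack(fill_value=0)
    )
    # keep MB columns in numeric order
    counts = counts[sorted(counts.columns, key=lambda c: int(str(c).split()[-1]))]
    totals = counts.sum(axis=1)
    comp = counts.div(totals, axis=0)
    comp.attrs["n_sbs"] = totals
    return comp


def spectrum_summary(
    labels: Sequence[str] | np.ndarray,
    substitutions: Sequence[CanonicalSubstitution],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-MB substitution-type and flank base-composition spectra.

    ``substitutions`` are the pyrimidine-collapsed sequences, aligned
    with ``labels``.  Returns (type_fractions, position_fractions):
    type_fractions is MB x 6 canonical types; position_fractions is tidy
    with columns mb, position (-F..-1, +1..+F), base (A/C/G/T/N) and
    fraction, where fractions sum to 1 at every (mb, position).
    """
    labels = np.asarray(labels)
    if labels.size != len(substitutions):
        raise ValueError("labels/substitutions length mismatch")
    F = len(substitutions[0].five_prime_flank)
    mbs = pd.unique(labels)

    type_rows = {}
    pos_rows = []
    positions = np.concatenate([np.arange(-F, 0), np.arange(1, F + 1)])
    for mb in mbs:
        idx = np.nonzero(labels == mb)[0]
        subs = [substitutions[i] for i in idx]
        type_counts = pd.Series([s.sub_type for s in subs]).value_counts()
        type_rows[mb] = [
            type_counts.get(t, 0) / len(subs) for t in CANONICAL_TYPES
        ]
        flanks = np.array(
            [list(s.five_prime_flank + s.three_prime_flank) for s in subs]
        )
        for j, pos in enumerate(positions):
            col = flanks[:, j]
            for base in "ACGTN":
                pos_rows.append(
                    {
                        "mb": mb,
                        "position": int(pos),
                        "base": base,
                        "fraction": float((col == base).mean()),
                    }
                )
    type_df = pd.DataFrame.from_dict(
        type_rows, orient="index", columns=list(CANONICAL_TYPES)
    )
    type_df.index.name = "mb"
    return type_df, pd.DataFrame(pos_rows)


def _wcss_curve(X: np.ndarray, k_range: Sequence[int], seed: int) -> pd.Series:
    wcss = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        wcss[k] = float(km.inertia_)
    return pd.Series(wcss).sort_index()


def elbow_k(wcss: pd.Series) -> int:
    """Knee of the dispersion curve: the k maximizing the second
    difference WCSS(k-1) - 2 WCSS(k) + WCSS(k+1) over interior points."""
    if len(wcss) < 3:
        raise ValueError("elbow selection needs at least 3 k values")
    ks = wcss.index.to_numpy()
    vals = wcss.to_numpy()
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    return int(ks[1:-1][int(np.argmax(second))])


def cluster_patients(
    comp: pd.DataFrame,
    K: int | str = 7,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
) -> PatientClassing:
    """K-means classes over MB-composition rows.

    ``K`` may be a fixed integer (default 7) or "auto", in which case the
    within-cluster sum of squares is computed over ``k_range`` and the
    knee (maximum second difference) is chosen.
    """
    if comp.empty:
        raise ValueError("empty composition matrix")
    X = comp.to_numpy(dtype=float)
    curve = None
    if K == "auto":
        curve = _wcss_curve(X, list(k_range), seed)
        K = elbow_k(curve)
    K = int(K)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds number of patients ({X.shape[0]})")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # canonical numbering: Class 1 is the largest
    order = np.argsort(-np.bincount(raw, minlength=K), kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(1, K + 1)
    classes = pd.Series(remap[raw], index=comp.index, name="patient_class")
    return PatientClassing(classes=classes, chosen_k=K, dispersion_curve=curve)


def group_compare(
    values: pd.Series | Sequence,
    grouping: pd.Series | Sequence,
    kind: str = "auto",
) -> TestResult:
    """Compare an outcome across groups with the matching classical test.

    Numeric outcomes: two-sample t test for 2 groups, one-way ANOVA for
    more.  Categorical outcomes: chi-square on the contingency table
    (Yates continuity correction on 2x2 tables).  Rows missing either the
    outcome or the group are dropped and counted.
    """
    df = pd.DataFrame({"value": pd.Series(values).reset_index(drop=True),
                       "group": pd.Series(grouping).reset_index(drop=True)})
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if kind == "auto":
        kind = "numeric" if pd.api.types.is_numeric_dtype(df["value"]) else "categorical"

    group_names = [g for g, _ in df.groupby("group", observed=True)]
    if len(group_names) < 2:
        raise ValueError(
            f"need >= 2 non-empty groups after missing-row removal, "
            f"got {group_names}"
        )
    sizes = df.groupby("group", observed=True).size().to_dict()

    if kind == "numeric":
        samples = [g["value"].to_numpy(dtype=float)
                   for _, g in df.groupby("group", observed=True)]
        if len(samples) == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1])
            name = "t-test"
        else:
            stat, p = stats.f_oneway(*samples)
            name = "anova"
    elif kind == "categorical":
        table = pd.crosstab(df["value"], df["group"])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            raise ValueError("contingency table has an empty margin")
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy())
        name = "chi-square"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return TestResult(
        statistic=float(stat), p_value=float(p), test_name=name,
        group_sizes=sizes, dropped_rows=dropped,
    )


def logrank(groups: Mapping[str, tuple[Sequence, Sequence]]) -> TestResult:
    """Log-rank test across >= 2 survival groups.

    ``groups`` maps a group name to (survival_times, event_indicators).
    Raises if no group contributes any event.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    times, events, labels = [], [], []
    sizes = {}
    for name, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size != e.size:
            raise ValueError(f"group {name!r}: times/events length mismatch")
        times.append(t)
        events.append(e)
        labels.extend([name] * t.size)
        sizes[name] = int(t.size)
    times = np.concatenate(times)
    events = np.concatenate(events)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return TestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        test_name="log-rank", group_sizes=sizes,
    )


def gene_mb_survival_groups(
    labels_frame: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str,
    mode: str = "all",
    patient_level: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Survival groups by the MB class of a given gene's mutations.

    ``mode``: "all" (default) puts a patient in every MB group it carries
    for the gene; "exclusive" keeps only patients with a single MB class
    in the gene; "drop" excludes multi-MB patients entirely (same as
    exclusive here, retained as an explicit alias).  Patients missing
    survival data are dropped.
    """
    if mode not in ("all", "exclusive", "drop"):
        raise ValueError(f"unknown mode {mode!r}")
    df = labels_frame[labels_frame["gene_symbol"] == gene]
    if df.empty:
        raise ValueError(f"no mutations recorded for gene {gene!r}")
    barcodes = df["sample_barcode"]
    if patient_level:
        barcodes = barcodes.str.split("-").str[:3].str.join("-")
    pairs = pd.DataFrame({"patient": barcodes, "mb": df["mb"]}).drop_duplicates()
    if mode in ("exclusive", "drop"):
        n_mb = pairs.groupby("patient")["mb"].nunique()
        keep = n_mb[n_mb == 1].index
        pairs = pairs[pairs["patient"].isin(keep)]

    clin = clinical.dropna(subset=["survival_time", "event"])
    groups = {}
    for mb, sub in pairs.groupby("mb"):
        patients = [p for p in sub["patient"] if p in clin.index]
        if not patients:
            continue
        rows = clin.loc[patients]
        groups[str(mb)] = (
            rows["survival_time"].to_numpy(dtype=float),
            rows["event"].to_numpy(dtype=int),
        )
    return groups


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival step function as a plain table
    (columns: time, survival) for external plotting."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    return sf
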