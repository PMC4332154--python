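"""Essentiality scoring from insertion-free gaps.

The null model: with ``N`` insertions placed uniformly on a circular
genome of length ``G``, the probability that a given span of length
``L`` receives none of them is

    P_N(L) = (1 - L/G)^N.

A maximal insertion-free interval is *significant* when P_N(L) <= alpha
(default 0.01, i.e. 99% confidence): the gap is too long to be a chance
hole in the insertion coverage, so the sequence inside it must not be
disruptable. Per region two probabilities are reported, rounded
half-up to two decimals:

* ``P_E`` — fraction of the region covered by significant
  insertion-free intervals (evidence of essentiality);
* ``P_NE`` — fraction of the region covered by the +-w bp
  neighborhoods of threshold-passing insertions *inside* the region
  (direct evidence of dispensability). The default radius
  w = ceil(G / 2N), half the mean inter-insertion spacing, makes the
  neighborhoods tile the genome at the observed insertion density.

Classification: E iff P_E > 0 and P_NE = 0; NE iff P_E = 0 and
P_NE > 0; otherwise F (fitness) — covering both the mixed-evidence
case (both > 0, typically genes whose domains differ in essentiality)
and the no-evidence case (both = 0, regions too short to call).

Read thresholds are calibrated from gold sets of known essential and
non-essential genes: for each candidate threshold t the error is the
number of gold-essential insertions kept (reads >= t) plus the number
of gold-non-essential insertions lost (reads < t); the relaxed and
stringent thresholds are the smallest and largest minimizers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .annotation import GenomeAnnotation
from .calling import InsertionTable

CATEGORIES = ("E", "NE", "F")


def round2(numerator: int, denominator: int) -> float:
    """Round numerator/denominator half-up to two decimals, exactly.

    Integer arithmetic avoids float half-way artifacts: 0.005 -> 0.01,
    anything below 0.005 -> 0.00.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return ((200 * numerator + denominator) // (2 * denominator)) / 100.0


def gap_null_probability(L: int, N: int, G: int) -> float:
    """P_N(L) = (1 - L/G)^N, computed in log space.

    The chance that a span of ``L`` bp receives none of ``N`` uniform
    insertions on a genome of ``G`` bp.
    """
    if G <= 0 or L < 0 or N < 0 or L > G:
        raise ValueError(f"invalid inputs L={L}, N={N}, G={G}")
    if N == 0 or L == 0:
        return 1.0
    if L == G:
        return 0.0
    return math.exp(N * math.log1p(-L / G))


def classify_call(P_E: float, P_NE: float) -> str:
    """Three-way E/NE/F rule on the two-decimal probabilities."""
    if not (0 <= P_E <= 1 and 0 <= P_NE <= 1):
        raise ValueError(f"probabilities outside [0,1]: {P_E}, {P_NE}")
    if P_E > 0 and P_NE == 0:
        return "E"
    if P_E == 0 and P_NE > 0:
        return "NE"
    return "F"


@dataclass
class GoldSet:
    """Curated genes of known essentiality for calibration."""

    essential_ids: list[str]
    nonessential_ids: list[str]

    def __post_init__(self) -> None:
        if not self.essential_ids or not self.nonessential_ids:
            raise ValueError("both gold classes must be non-empty")
        overlap = set(self.essential_ids) & set(self.nonessential_ids)
        if overlap:
            raise ValueError(f"gold sets not disjoint: {sorted(overlap)[:3]}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gid in self.essential_ids:
                fh.write(f"{gid}\tE\n")
            for gid in self.nonessential_ids:
                fh.write(f"{gid}\tNE\n")

    @classmethod
    def from_tsv(cls, path) -> "GoldSet":
        ess, non = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                gid, cls_ = line.split("\t")[:2]
                (ess if cls_.strip() == "E" else non).append(gid.strip())
        return cls(ess, non)


@dataclass
class ScoringModel:
    """Calibrated parameters of the gap-null scoring."""

    G: int
    N: int
    alpha: float = 0.01
    read_threshold: int = 1
    w: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.w is None:
            if self.N > 0:
                self.w = max(1, math.ceil(self.G / (2 * self.N)))
        elif not 1 <= self.w <= self.G:
            raise ValueError("w must be in [1, G]")

    @classmethod
    def from_table(
        cls,
        table: InsertionTable,
        alpha: float = 0.01,
        read_threshold: int = 1,
        w: int | None = None,
        circular: bool = True,
    ) -> "ScoringModel":
        positions = table.merged_positions(read_threshold)
        return cls(
            G=table.G,
            N=int(positions.size),
            alpha=alpha,
            read_threshold=read_threshold,
            w=w,
            circular=circular,
        )


@dataclass
class EssentialityCall:
    region_id: str
    P_E: float
    P_NE: float
    category: str
    n_insertions: int
    longest_gap: int


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by possibly-overlapping [start, end] intervals."""
    if starts.size == 0:
        return 0
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    total, cs, ce = 0, s[0], e[0]
    for i in range(1, s.size):
        if s[i] <= ce + 1:
            ce = max(ce, e[i])
        else:
            total += ce - cs + 1
            cs, ce = s[i], e[i]
    return int(total + ce - cs + 1)


class GenomeScorer:
    """Precomputes insertion-free intervals once, scores many regions.

    ``positions`` are the orientation-merged, threshold-passing site
    coordinates. Intervals are computed on the circular genome (the
    wrap-around gap is carried in extended coordinates past G).
    """

    def __init__(self, positions: np.ndarray, model: ScoringModel):
        positions = np.unique(np.asarray(positions, dtype=np.int64))
        if positions.size == 0:
            raise ValueError(
                "no threshold-passing insertions (N=0): scoring is degenerate; "
                "see the documented zero-insertion case"
            )
        if positions[0] < 1 or positions[-1] > model.G:
            raise ValueError("site position outside [1, G]")
        self.positions = positions
        self.model = model
        G, N = model.G, positions.size
        if model.circular:
            gs = positions + 1
            ge = np.concatenate([positions[1:] - 1, [positions[0] - 1 + G]])
        else:
            gs = np.concatenate([[1], positions + 1])
            ge = np.concatenate([positions - 1, [G]])
        lengths = ge - gs + 1
        keep = lengths >= 1
        self.gap_starts, self.gap_ends = gs[keep], ge[keep]
        self.gap_lengths = lengths[keep]
        pvals = np.array(
            [gap_null_probability(int(min(L, G)), model.N, G) for L in self.gap_lengths]
        )
        sig = pvals <= model.alpha
        self.sig_starts = self.gap_starts[sig]
        self.sig_ends = self.gap_ends[sig]

    # ------------------------------------------------------------- scoring

    def _overlap_with(self, starts, ends, a: int, b: int, longest: bool = False):
        """Overlap of [a,b] with intervals given in extended circular
        coordinates (each also considered shifted by -G)."""
        G = self.model.G
        best, total = 0, 0
        for shift in (0, -G):
            s = starts + shift
            e = ends + shift
            ov = np.minimum(e, b) - np.maximum(s, a) + 1
            ov = ov[ov > 0]
            total += int(ov.sum())
            if ov.size:
                best = max(best, int(ov.max()))
        return best if longest else total

    def score(self, start: int, end: int, region_id: str = "region") -> EssentialityCall:
        G = self.model.G
        if not (1 <= start <= G and 1 <= end <= G):
            raise ValueError(f"region {region_id} outside genome")
        if start > end:
            if not self.model.circular:
                raise ValueError("wrapping region on a linear genome")
            # rotate so the region becomes linear; scores are rotation-invariant
            shift = start - 1
            rot = (self.positions - 1 - shift) % G + 1
            return GenomeScorer(rot, self.model).score(1, end + G - start + 1, region_id)
        length = end - start + 1
        cov_e = self._overlap_with(self.sig_starts, self.sig_ends, start, end)
        inside = self.positions[(self.positions >= start) & (self.positions <= end)]
        w = self.model.w
        nbh_s = np.maximum(inside - w, start)
        nbh_e = np.minimum(inside + w, end)
        cov_ne = _union_length(nbh_s, nbh_e)
        longest = self._overlap_with(self.gap_starts, self.gap_ends, start, end, longest=True)
        P_E = round2(cov_e, length)
        P_NE = round2(cov_ne, length)
        return EssentialityCall(
            region_id=region_id,
            P_E=P_E,
            P_NE=P_NE,
            category=classify_call(P_E, P_NE),
            n_insertions=int(inside.size),
            longest_gap=int(longest),
        )

    def score_features(self, features: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for f in features.itertuples():
            call = self.score(int(f.start), int(f.end), f.id)
            rows.append(
                (f.id, f.type, call.P_E, call.P_NE, call.category,
                 call.n_insertions, call.longest_gap)
            )
        return pd.DataFrame(
            rows,
            columns=["id", "type", "P_E", "P_NE", "category", "n_insertions", "longest_gap"],
        ).set_index("id")

    def essential_segments(self) -> pd.DataFrame:
        """Significant insertion-free intervals normalized to [1, G]
        (the wrap interval is split at the origin)."""
        G = self.model.G
        rows = []
        for s, e in zip(self.sig_starts, self.sig_ends):
            if e <= G:
                rows.append((int(s), int(e)))
            else:  # wraps past the origin
                if s <= G:
                    rows.append((int(s), G))
                rows.append((1, int(e - G)))
        rows.sort()
        return pd.DataFrame(rows, columns=["start", "end"])


def score_region(region, table: InsertionTable, model: ScoringModel) -> EssentialityCall:
    """Score one region; ``region`` is (start, end) or (id, start, end)."""
    if len(region) == 3:
        rid, start, end = region
    else:
        (start, end), rid = region, "region"
    scorer = GenomeScorer(table.merged_positions(model.read_threshold), model)
    return scorer.score(int(start), int(end), str(rid))


# -------------------------------------------------- timepoint and threshold


class TimepointError(RuntimeError):
    pass


def _insertions_per_gene(table: InsertionTable, genes: pd.DataFrame) -> np.ndarray:
    pos = table.df["position"].to_numpy()
    return np.array([((pos >= s) & (pos <= e)).sum() for s, e in zip(genes["start"], genes["end"])])


def select_timepoint(
    tables: dict[int, InsertionTable],
    gold: GoldSet,
    annotation: GenomeAnnotation,
    rel_drop: float = 0.1,
    floor: float = 0.5,
    ne_keep: float = 0.8,
):
    """Pick the analysis day: earliest where the essential gold set has
    (nearly) lost its insertions while the non-essential set kept them.

    Returns (day, diagnostics) where diagnostics has per-day mean
    insertion counts for both gold sets. Raises
    :class:`TimepointError` when no day qualifies (a failed experiment
    or library bottleneck).
    """
    if not tables:
        raise ValueError("at least one day required")
    feats = annotation.features.set_index("id")
    missing = [g for g in gold.essential_ids + gold.nonessential_ids if g not in feats.index]
    if missing:
        raise KeyError(f"gold genes absent from annotation: {missing[:3]}")
    e_genes = feats.loc[gold.essential_ids].reset_index()
    ne_genes = feats.loc[gold.nonessential_ids].reset_index()
    days = sorted(tables)
    diag = pd.DataFrame(
        {
            "e_mean": [_insertions_per_gene(tables[d], e_genes).mean() for d in days],
            "ne_mean": [_insertions_per_gene(tables[d], ne_genes).mean() for d in days],
        },
        index=pd.Index(days, name="day"),
    )
    e0, ne0 = diag["e_mean"].iloc[0], diag["ne_mean"].iloc[0]
    eps = max(rel_drop * e0, floor)
    for d in days:
        if diag.loc[d, "e_mean"] <= eps and diag.loc[d, "ne_mean"] >= ne_keep * ne0:
            if len(days) == 1:
                warnings.warn("single-day series: timepoint choice is unvalidated")
            return d, diag
    raise TimepointError(
        f"no day reaches E-mean <= {eps:.2f} with NE-mean >= {ne_keep:.0%} of day "
        f"{days[0]}:\n{diag}"
    )


@dataclass
class CalibrationResult:
    relaxed: int
    stringent: int
    curve: pd.DataFrame
    degenerate: bool = False


def calibrate_read_threshold(
    table: InsertionTable, gold: GoldSet, annotation: GenomeAnnotation
) -> CalibrationResult:
    """Exhaustive search for read thresholds separating the gold sets.

    error(t) = (# insertions in gold-essential genes with reads >= t)
             + (# insertions in gold-non-essential genes with reads < t),
    for t in [1, max reads + 1]. Relaxed/stringent are the smallest and
    largest minimizers.
    """
    feats = annotation.features.set_index("id")
    pos = table.df["position"].to_numpy()
    reads = table.df["reads"].to_numpy()

    def class_reads(ids):
        chunks = []
        for gid in ids:
            if gid not in feats.index:
                raise KeyError(f"gold gene {gid!r} absent from annotation")
            s, e = feats.loc[gid, "start"], feats.loc[gid, "end"]
            chunks.append(reads[(pos >= s) & (pos <= e)])
        return np.concatenate(chunks) if chunks else np.array([], dtype=int)

    e_reads = class_reads(gold.essential_ids)
    ne_reads = class_reads(gold.nonessential_ids)
    if e_reads.size == 0 or ne_reads.size == 0:
        raise ValueError("a gold class has zero insertions: calibration undefined")
    tmax = int(max(e_reads.max(), ne_reads.max())) + 1
    ts = np.arange(1, tmax + 1)
    err = np.array([(e_reads >= t).sum() + (ne_reads < t).sum() for t in ts])
    best = err.min()
    minimizers = ts[err == best]
    degenerate = len(np.unique(err)) == 1  # flat curve: no separation at all
    if degenerate:
        relaxed = stringent = int(ts[0])
        warnings.warn("degenerate calibration: gold read distributions do not separate")
    else:
        relaxed, stringent = int(minimizers.min()), int(minimizers.max())
    curve = pd.DataFrame({"threshold": ts, "error": err})
    return CalibrationResult(relaxed, stringent, curve, degenerate)


# ------------------------------------------------------ feature summaries


@dataclass
class ClassSummary:
    feature_class: str
    n: int
    counts: dict
    percentages: dict
    n_unassignable: int = 0


def assign_feature_essentiality(
    annotation: GenomeAnnotation, calls: pd.DataFrame, feature_class: str
) -> ClassSummary:
    """Per-class E/NE/F tally with the ncRNA overlap rule.

    ncRNAs overlapping an essential-called ORF on either strand are
    "unassignable" (their insertion-free state may only reflect the
    host). Intergenic regions are restricted to > 100 bp.
    """
    feats = annotation.features
    if feature_class == "intergenic":
        members = annotation.intergenic_regions(min_length=101)
    else:
        members = annotation.of_type(feature_class)
    ids = [i for i in members["id"] if i in calls.index]
    n_unassignable = 0
    if feature_class == "ncRNA" and ids:
        orf_calls = calls[calls["type"] == "ORF"] if "type" in calls else calls
        e_orfs = feats[
            (feats["type"] == "ORF")
            & (feats["id"].isin(orf_calls.index[orf_calls["category"] == "E"]))
        ]
        keep = []
        for nc in members.itertuples():
            if nc.id not in calls.index:
                continue
            hits = e_orfs[(e_orfs["start"] <= nc.end) & (e_orfs["end"] >= nc.start)]
            if len(hits):
                n_unassignable += 1
            else:
                keep.append(nc.id)
        ids = keep
    cats = calls.loc[ids, "category"] if ids else pd.Series(dtype=object)
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    n = len(ids)
    percentages = {c: (100.0 * counts[c] / n if n else 0.0) for c in CATEGORIES}
    return ClassSummary(feature_class, n, counts, percentages, n_unassignable)


@dataclass
class LandscapeSummary:
    segments: pd.DataFrame  # start, end (1-based inclusive, sorted)
    essential_bp: int
    essential_fraction: float
    class_summaries: dict = field(default_factory=dict)
    essential_intergenic: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None

    def to_bed(self, path, genome_id: str = "genome") -> None:
        with open(path, "w") as fh:
            for seg in self.segments.itertuples():
                fh.write(f"{genome_id}\t{seg.start - 1}\t{seg.end}\tessential\n")


def essential_landscape(
    annotation: GenomeAnnotation, table: InsertionTable, model: ScoringModel
) -> LandscapeSummary:
    """Genome-wide essentiality landscape.

    Essential segments are the significant insertion-free intervals;
    per-class summaries cover every annotated feature class present
    plus intergenic regions > 100 bp.
    """
    scorer = GenomeScorer(table.merged_positions(model.read_threshold), model)
    segments = scorer.essential_segments()
    essential_bp = int((segments["end"] - segments["start"] + 1).sum()) if len(segments) else 0

    to_score = annotation.features[annotation.features["type"] != "intergenic"]
    ig = annotation.intergenic_regions(min_length=101)
    all_feats = pd.concat([to_score, ig], ignore_index=True) if len(ig) else to_score
    calls = scorer.score_features(all_feats)

    classes = [c for c in ("ORF", "smORF", "ncRNA", "UTR5", "convRNA") if (all_feats["type"] == c).any()]
    summaries = {c: assign_feature_essentiality(annotation, calls, c) for c in classes}
    if len(ig):
        summaries["intergenic"] = assign_feature_essentiality(annotation, calls, "intergenic")
        ig_e = ig[ig["id"].isin(calls.index[calls["category"] == "E"])]
    else:
        ig_e = ig
    return LandscapeSummary(
        segments=segments,
        essential_bp=essential_bp,
        essential_fraction=essential_bp / model.G,
        class_summaries=summaries,
        essential_intergenic=ig_e.reset_index(drop=True),
        calls=calls,
    )


# ------------------------------------------------------- sklearn estimator


class EssentialityClassifier(BaseEstimator):
    """Gold-set-calibrated E/NE/F classifier over genomic regions.

    fit() calibrates the read threshold from the gold sets (or accepts
    an integer threshold), counts threshold-passing insertions and
    freezes the :class:`ScoringModel`; predict() returns E/NE/F per
    region. Region input is a DataFrame with ``start``/``end`` (and
    optionally ``id``/``type``) columns.

    Parameters
    ----------
    alpha : significance level of the gap null (default 0.01).
    read_threshold : "stringent", "relaxed", or an integer count.
    w : neighborhood radius in bp; None = ceil(G / 2N).
    circular : treat the genome as circular.
    """

    def __init__(self, alpha: float = 0.01, read_threshold="stringent",
                 w: int | None = None, circular: bool = True):
        self.alpha = alpha
        self.read_threshold = read_threshold
        self.w = w
        self.circular = circular

    def fit(self, table: InsertionTable, y=None, *, annotation=None, gold=None):
        if isinstance(self.read_threshold, str):
            if self.read_threshold not in ("relaxed", "stringent"):
                raise ValueError("read_threshold must be 'relaxed', 'stringent' or int")
            if gold is None or annotation is None:
                raise ValueError("gold set and annotation required for calibration")
            cal = calibrate_read_threshold(table, gold, annotation)
            self.calibration_ = cal
            threshold = cal.relaxed if self.read_threshold == "relaxed" else cal.stringent
        else:
            threshold = int(self.read_threshold)
            self.calibration_ = None
        self.model_ = ScoringModel.from_table(
            table, alpha=self.alpha, read_threshold=threshold,
            w=self.w, circular=self.circular,
        )
        self.scorer_ = GenomeScorer(table.merged_positions(threshold), self.model_)
        self.n_sites_ = self.model_.N
        return self

    def _check_fitted(self):
        if not hasattr(self, "scorer_"):
            raise RuntimeError("EssentialityClassifier is not fitted")

    def score_regions(self, regions: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        regions = regions.copy()
        if "id" not in regions.columns:
            regions["id"] = [f"region_{i}" for i in range(len(regions))]
        if "type" not in regions.columns:
            regions["type"] = "region"
        return self.scorer_.score_features(regions)

    def predict(self, regions: pd.DataFrame) -> np.ndarray:
        return self.score_regions(regions)["category"].to_numpy()
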