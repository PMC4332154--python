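"""ncRNA co-expression and smORF analyses.

Antisense ncRNAs that overlap protein-coding genes may regulate them;
over a growth time course their expression then co-varies with the
host ORF's. Pairwise association is scored with CLR (context
likelihood of relatedness): the mutual information of each pair is
z-scored against the background MI distribution of both partners, so
hub-driven background correlation is cancelled. With ~10 timepoints a
binned MI estimate is unstable, so MI is taken from the Gaussian
(copula) identity MI = -1/2 ln(1 - r^2), which is monotone in |r| and
well behaved at small n. The pair score is the mean of the two clamped
z-scores; pairs above a fixed threshold (2.5) are significant, and the
sign of Pearson's r labels them correlated or anti-correlated.

Whether anti-correlated partners are enriched for essential ORFs is
tested with Welch's two-sample t-test on the per-ncRNA percentages of
essential partners.

smORF candidates are found by three-frame translation of ncRNA
sequences under genetic code 4 (UGA = Trp): maximal start-to-stop
spans yielding peptides of < 100 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .seq import VALID_NT, revcomp, translate_code4

CLR_THRESHOLD_DEFAULT = 2.5
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


# ----------------------------------------------------------------- CLR


def _clr_scores(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pearson r, MI, clr) square matrices for rows-of-features X."""
    n = X.shape[0]
    sd = X.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance feature(s): MI set to 0")
        X = X.copy()
        X[zero_var] += np.random.default_rng(0).normal(0, 1e-12, size=(int(zero_var.sum()), X.shape[1]))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    mi = -0.5 * np.log1p(-np.clip(r * r, 0.0, 1.0 - 1e-15))
    mu = np.empty(n)
    sigma = np.empty(n)
    for i in range(n):
        row = np.delete(mi[i], i)
        mu[i] = row.mean()
        sigma[i] = row.std()
    sigma[sigma == 0] = 1.0
    z = np.maximum(0.0, (mi - mu[:, None]) / sigma[:, None])
    clr = (z + z.T) / 2.0
    np.fill_diagonal(clr, 0.0)
    return r, mi, clr


class CLRNetwork(BaseEstimator):
    """CLR association network over an expression matrix.

    fit(X) with X a features-by-timepoints DataFrame computes the full
    pairwise matrices; ``pairs()`` returns the tidy upper-triangle
    listing with significance at the configured threshold.
    """

    def __init__(self, threshold: float = CLR_THRESHOLD_DEFAULT):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] < 3:
            raise ValueError("at least 3 timepoints required")
        if X.shape[0] < 3:
            raise ValueError("at least 3 features required (background undefined)")
        if X.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if X.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        self.feature_names_ = list(X.index)
        self.pearson_, self.mi_, self.clr_ = _clr_scores(X.to_numpy(dtype=float))
        return self

    def transform(self, X=None) -> pd.DataFrame:
        self._check_fitted()
        return pd.DataFrame(self.clr_, index=self.feature_names_, columns=self.feature_names_)

    def _check_fitted(self):
        if not hasattr(self, "clr_"):
            raise RuntimeError("CLRNetwork is not fitted")

    def pairs(self) -> pd.DataFrame:
        self._check_fitted()
        names = self.feature_names_
        iu, ju = np.triu_indices(len(names), k=1)
        df = pd.DataFrame(
            {
                "feature_i": np.array(names)[iu],
                "feature_j": np.array(names)[ju],
                "mi": self.mi_[iu, ju],
                "clr_score": self.clr_[iu, ju],
                "pearson_r": self.pearson_[iu, ju],
            }
        )
        df["significant"] = df["clr_score"] > self.threshold
        return df

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        """(clr score, pearson r) for one pair."""
        self._check_fitted()
        try:
            i = self.feature_names_.index(a)
            j = self.feature_names_.index(b)
        except ValueError as err:
            raise KeyError(f"pair ({a}, {b}) absent from matrix") from err
        return float(self.clr_[i, j]), float(self.pearson_[i, j])


def clr_matrix(expr: pd.DataFrame, threshold: float = CLR_THRESHOLD_DEFAULT) -> CLRNetwork:
    """Fit a :class:`CLRNetwork` on a features-by-timepoints matrix."""
    return CLRNetwork(threshold=threshold).fit(expr)


def classify_pairs(
    net: CLRNetwork, pairs_of_interest: pd.DataFrame,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Sign significant pairs: anti-correlated (r < 0), correlated
    (r > 0) or undetermined (r = 0, excluded downstream).

    ``pairs_of_interest`` needs columns (ncrna, orf); both members must
    be in the fitted matrix.
    """
    thr = net.threshold if threshold is None else threshold
    rows = []
    for p in pairs_of_interest.itertuples():
        clr, r = net.lookup(p.ncrna, p.orf)
        if clr > thr:
            sign = "anti-correlated" if r < 0 else ("correlated" if r > 0 else "undetermined")
        else:
            sign = "not significant"
        rows.append((p.ncrna, p.orf, clr, r, sign))
    return pd.DataFrame(rows, columns=["ncrna", "orf", "clr_score", "pearson_r", "sign"])


# ------------------------------------------------------------ Welch test


@dataclass
class WelchResult:
    t: float
    df: float
    pvalue: float
    mean1: float
    mean2: float
    n1: int
    n2: int


def welch_ttest(sample1, sample2) -> WelchResult:
    """Welch's two-sample t-test (two-sided), df by Welch-Satterthwaite.

    Groups with zero pooled variance and equal means return t=0, p=1 by
    convention; zero variance with different means gives p=0.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2 (variance undefined)")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, m1, m2, n1, n2)
        return WelchResult(float("inf") if m1 > m2 else float("-inf"),
                           float(n1 + n2 - 2), 0.0, m1, m2, n1, n2)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(m1), float(m2), n1, n2)


def essentiality_enrichment(
    signed_pairs: pd.DataFrame, calls: pd.DataFrame
) -> tuple[WelchResult, pd.DataFrame]:
    """Are anti-correlated ORF partners more often essential?

    Per ncRNA: the percentage of its anti-correlated partners that are
    called E, and likewise for correlated partners; the two per-ncRNA
    percentage samples are compared by Welch's t-test.

    ``signed_pairs`` from :func:`classify_pairs`; ``calls`` indexed by
    ORF id with a ``category`` column.
    """
    sig = signed_pairs[signed_pairs["sign"].isin(["anti-correlated", "correlated"])]
    if not len(sig):
        raise ValueError("no signed pairs")
    missing = [o for o in sig["orf"].unique() if o not in calls.index]
    if missing:
        raise KeyError(f"ORFs without essentiality calls: {missing[:3]}")
    rows = []
    for nc, grp in sig.groupby("ncrna"):
        for sign_label, key in (("anti-correlated", "pct_e_anti"), ("correlated", "pct_e_corr")):
            part = grp[grp["sign"] == sign_label]
            if len(part):
                pct = 100.0 * (calls.loc[part["orf"], "category"] == "E").mean()
                rows.append((nc, key, pct, len(part)))
    per_ncrna = pd.DataFrame(rows, columns=["ncrna", "which", "pct_essential", "n_partners"])
    anti = per_ncrna.loc[per_ncrna["which"] == "pct_e_anti", "pct_essential"]
    corr = per_ncrna.loc[per_ncrna["which"] == "pct_e_corr", "pct_essential"]
    result = welch_ttest(anti, corr)
    return result, per_ncrna


# ----------------------------------------------------------- smORF scan


def scan_smorfs(
    sequences: dict[str, str] | pd.Series,
    min_aa: int = 10,
    max_aa: int = 99,
    start_codons=DEFAULT_START_CODONS,
) -> pd.DataFrame:
    """Three-frame smORF scan under genetic code 4.

    For each sequence and each forward frame, maximal start-to-stop
    spans (5'-most start per stop) with peptide length within
    [min_aa, max_aa]. TGA is read as tryptophan; only TAA/TAG stop.

    Returns columns: seq_id, frame (1-3), nt_start, nt_end (1-based in
    the given sequence), aa_length, peptide.
    """
    if isinstance(sequences, pd.Series):
        sequences = dict(sequences)
    starts = {c.upper() for c in start_codons}
    rows = []
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
        seq = str(seq).upper()
        bad = set(seq) - VALID_NT
        if bad:
            raise ValueError(f"invalid nucleotide {sorted(bad)[0]!r} in {sid!r}")
        for frame in (1, 2, 3):
            codons = [seq[i : i + 3] for i in range(frame - 1, len(seq) - 2, 3)]
            open_at = None
            for ci, cod in enumerate(codons):
                if open_at is None and cod in starts:
                    open_at = ci
                elif open_at is not None and cod in ("TAA", "TAG"):
                    aa_len = ci - open_at
                    if min_aa <= aa_len <= max_aa:
                        nt_start = frame + 3 * open_at
                        nt_end = frame + 3 * (ci + 1) - 1
                        cds = seq[nt_start - 1 : nt_end]
                        peptide = translate_code4(cds)[:-1]  # drop '*'
                        rows.append((sid, frame, nt_start, nt_end, aa_len, peptide))
                    open_at = None
    return pd.DataFrame(
        rows, columns=["seq_id", "frame", "nt_start", "nt_end", "aa_length", "peptide"]
    )


def smorfs_on_genome(
    annotation, genome: str, min_aa: int = 10, max_aa: int = 99,
    start_codons=DEFAULT_START_CODONS,
) -> pd.DataFrame:
    """Scan every annotated ncRNA (on its annotated strand) for smORF
    candidates; adds genome coordinates of each candidate."""
    ncrnas = annotation.of_type("ncRNA")
    seqs = {}
    for nc in ncrnas.itertuples():
        s = genome[nc.start - 1 : nc.end]
        seqs[nc.id] = s if nc.strand != "-" else revcomp(s)
    if not seqs:
        return pd.DataFrame(
            columns=["seq_id", "frame", "nt_start", "nt_end", "aa_length", "peptide",
                     "genome_start", "genome_end", "strand"]
        )
    hits = scan_smorfs(seqs, min_aa=min_aa, max_aa=max_aa, start_codons=start_codons)
    feats = ncrnas.set_index("id")
    g_start, g_end, strand = [], [], []
    for h in hits.itertuples():
        nc = feats.loc[h.seq_id]
        if nc["strand"] != "-":
            g_start.append(nc["start"] + h.nt_start - 1)
            g_end.append(nc["start"] + h.nt_end - 1)
        else:
            g_start.append(nc["end"] - h.nt_end + 1)
            g_end.append(nc["end"] - h.nt_start + 1)
        strand.append(nc["strand"])
    hits["genome_start"] = g_start
    hits["genome_end"] = g_end
    hits["strand"] = strand
    return hits
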