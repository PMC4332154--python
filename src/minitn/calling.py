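"""Insertion-site discovery from transposon-junction reads.

A junction read begins with the transposon's terminal inverted repeat
(IR); the genomic flank that follows pins the insertion to a single
coordinate. The stages are: IR filtering (authenticate and trim),
flank mapping (unique exact k-mer seed match against the reference,
both strands), and collapsing raw calls into a deduplicated,
read-counted insertion table.

Coordinate convention: the site position is the 1-based coordinate of
the first genomic base downstream of the IR on the read's orientation.
For a '+' read the flank equals ``genome[p..]``; for a '-' read it is
the reverse complement of ``genome[..p]``. Opposite-orientation sites
at one position are kept distinct (the mini-transposon carries an
internal promoter, so orientation is biologically meaningful); they
are merged only for essentiality scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seq import check_nucleotides, circular_slice, kmer_index, revcomp

SITE_COLUMNS = ["position", "orientation", "reads", "sample", "day"]

#: provenance buckets; every input read lands in exactly one
PROVENANCE_KEYS = ("total", "no_ir", "unmapped", "ambiguous", "mapped")


def empty_provenance() -> dict[str, int]:
    return {k: 0 for k in PROVENANCE_KEYS}


@dataclass
class InsertionTable:
    """Unique transposon insertion sites with per-site read counts."""

    df: pd.DataFrame
    G: int
    genome_id: str = "genome"
    provenance: dict[str, int] = field(default_factory=empty_provenance)

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"insertion table missing columns {missing}")
        d = self.df
        if len(d):
            if (d["position"] < 1).any() or (d["position"] > self.G).any():
                raise ValueError("site position outside [1, G]")
            if (d["reads"] < 1).any():
                raise ValueError("site with reads < 1")
            if d.duplicated(subset=["position", "orientation", "sample"]).any():
                raise ValueError("duplicate (position, orientation, sample) site")
        tot = self.provenance.get("total", 0)
        parts = sum(self.provenance.get(k, 0) for k in PROVENANCE_KEYS[1:])
        if tot and tot != parts:
            raise ValueError("provenance counts do not sum to total")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum())

    def merged_positions(self, read_threshold: int = 1) -> np.ndarray:
        """Orientation-merged unique site positions whose summed read
        count passes ``read_threshold`` (sorted, 1-based)."""
        sums = self.df.groupby("position")["reads"].sum()
        return np.sort(sums[sums >= read_threshold].index.to_numpy(dtype=np.int64))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genome_id\t{self.genome_id}\n")
            fh.write(f"# G\t{self.G}\n")
            for k in PROVENANCE_KEYS:
                fh.write(f"# provenance_{k}\t{self.provenance.get(k, 0)}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InsertionTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        prov = {
            k: int(meta.get(f"provenance_{k}", 0)) for k in PROVENANCE_KEYS
        }
        return cls(
            df=df.astype({"position": int, "reads": int, "day": int}),
            G=int(meta["G"]),
            genome_id=meta.get("genome_id", "genome"),
            provenance=prov,
        )

    def to_wig(self, path) -> None:
        """Per-position read sums, WIG variableStep (1-based)."""
        sums = self.df.groupby("position")["reads"].sum().sort_index()
        with open(path, "w") as fh:
            fh.write(f"variableStep chrom={self.genome_id}\n")
            for p, r in sums.items():
                fh.write(f"{p}\t{r}\n")

    def to_bed(self, path) -> None:
        """Site intervals as BED (0-based half-open, score = reads)."""
        with open(path, "w") as fh:
            for row in self.df.itertuples():
                fh.write(
                    f"{self.genome_id}\t{row.position - 1}\t{row.position}\t"
                    f"site\t{row.reads}\t{row.orientation}\n"
                )


# ---------------------------------------------------------------- operations


def filter_by_inverted_repeat(reads, ir_tag: str, max_mismatch: int = 0):
    """Authenticate junction reads by their IR prefix and trim it.

    Parameters
    ----------
    reads : iterable of Bio.SeqRecord or (id, sequence) pairs
    ir_tag : expected IR prefix
    max_mismatch : tolerated substitutions within the prefix

    Returns
    -------
    (flanks, n_discarded) : list of (id, flank_sequence), int
    """
    if not ir_tag:
        raise ValueError("ir_tag must be non-empty")
    ir = ir_tag.upper()
    n = len(ir)
    flanks: list[tuple[str, str]] = []
    discarded = 0
    for rec in reads:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq).upper()
        else:
            rid, seq = rec[0], str(rec[1]).upper()
        prefix = seq[:n]
        if len(prefix) == n and sum(a != b for a, b in zip(prefix, ir)) <= max_mismatch:
            flanks.append((rid, seq[n:]))
        else:
            discarded += 1
    return flanks, discarded


def map_flanks(flanks, genome: str, k: int = 20, circular: bool = True):
    """Map trimmed flanks to the reference by unique exact k-mer seed.

    Each flank whose first ``k`` bases occur at exactly one locus in the
    genome (forward or reverse-complement, the origin wrap included for
    circular genomes) yields a raw site call at the junction coordinate.
    Multi-locus seeds are counted ambiguous; absent seeds unmapped.

    Returns (calls DataFrame [position, orientation], counts dict).
    """
    if k < 12:
        raise ValueError("k < 12: seed too short to be unambiguous on a ~816 kb genome")
    G = len(genome)
    genome = genome.upper()
    index = kmer_index(genome, k, circular=circular)
    rows = []
    counts = {"mapped": 0, "ambiguous": 0, "unmapped": 0}
    for _rid, flank in flanks:
        seed = flank[:k].upper()
        if len(seed) < k:
            counts["unmapped"] += 1
            continue
        fwd = index.get(seed, [])
        rev = index.get(revcomp(seed), [])
        if len(fwd) + len(rev) == 1:
            if fwd:
                pos, ori = fwd[0], "+"
            else:
                pos, ori = (rev[0] + k - 2) % G + 1, "-"
            rows.append((pos, ori))
            counts["mapped"] += 1
        elif fwd or rev:
            counts["ambiguous"] += 1
        else:
            counts["unmapped"] += 1
    calls = pd.DataFrame(rows, columns=["position", "orientation"])
    return calls, counts


def collapse_sites(
    calls: pd.DataFrame,
    G: int,
    genome_id: str = "genome",
    sample: str = "sample",
    day: int = 0,
    provenance: dict[str, int] | None = None,
) -> InsertionTable:
    """Aggregate raw calls into unique (position, orientation) sites,
    reads = number of supporting calls, sorted by position."""
    if len(calls):
        grouped = (
            calls.groupby(["position", "orientation"])
            .size()
            .rename("reads")
            .reset_index()
            .sort_values(["position", "orientation"], kind="stable")
            .reset_index(drop=True)
        )
        grouped["sample"] = sample
        grouped["day"] = day
        df = grouped[SITE_COLUMNS]
    else:
        df = pd.DataFrame(columns=SITE_COLUMNS).astype(
            {"position": int, "reads": int, "day": int, "orientation": str, "sample": str}
        )
    return InsertionTable(
        df=df, G=G, genome_id=genome_id, provenance=provenance or empty_provenance()
    )


def call_insertions(
    reads,
    genome: str,
    ir_tag: str,
    k: int = 20,
    max_mismatch: int = 0,
    genome_id: str = "genome",
    sample: str = "sample",
    day: int = 0,
    circular: bool = True,
) -> InsertionTable:
    """Full read-to-table stage: IR filter, map, collapse, with provenance."""
    reads = list(reads)
    flanks, no_ir = filter_by_inverted_repeat(reads, ir_tag, max_mismatch)
    calls, counts = map_flanks(flanks, genome, k=k, circular=circular)
    provenance = {
        "total": len(reads),
        "no_ir": no_ir,
        "unmapped": counts["unmapped"],
        "ambiguous": counts["ambiguous"],
        "mapped": counts["mapped"],
    }
    return collapse_sites(
        calls, G=len(genome), genome_id=genome_id, sample=sample, day=day,
        provenance=provenance,
    )


# ----------------------------------------------------- composition bias


@dataclass
class QuadrupletBiasReport:
    per_kmer: pd.DataFrame
    gc_rich_ratio: float
    chi2: float
    dof: int
    pvalue: float


def _junction_kmer(genome: str, position: int) -> str:
    # 4-mer centred on the junction: bases p-2 .. p+1 (circular)
    return circular_slice(genome, position - 2, 4)


def quadruplet_bias(
    table: InsertionTable, genome: str, read_threshold: int = 1
) -> QuadrupletBiasReport:
    """Per-quadruplet insertion enrichment around the junction.

    For each of the 256 quadruplets: observed insertions whose
    junction-centred 4-mer (bases p-2..p+1, circular) equals it,
    expected under uniform insertion = N * (genome occurrences / G),
    their ratio, and a chi-square goodness-of-fit over represented
    quadruplets. ``gc_rich_ratio`` summarises the class of quadruplets
    with >= 3 G/C bases.
    """
    G = len(genome)
    if G < 4:
        raise ValueError("genome shorter than 4 bp")
    positions = table.merged_positions(read_threshold)
    if positions.size == 0:
        raise ValueError("empty insertion table: bias undefined")
    check_nucleotides(genome, "genome")
    genome = genome.upper()

    genome_counts: dict[str, int] = {}
    for p in range(1, G + 1):
        kmer = _junction_kmer(genome, p)
        genome_counts[kmer] = genome_counts.get(kmer, 0) + 1
    obs_counts: dict[str, int] = {}
    for p in positions:
        kmer = _junction_kmer(genome, int(p))
        obs_counts[kmer] = obs_counts.get(kmer, 0) + 1

    from itertools import product

    N = positions.size
    rows = []
    for kmer_t in product("ACGT", repeat=4):
        kmer = "".join(kmer_t)
        occ = genome_counts.get(kmer, 0)
        obs = obs_counts.get(kmer, 0)
        exp = N * occ / G
        gc = sum(b in "GC" for b in kmer)
        rows.append((kmer, gc, obs, occ, exp, obs / exp if exp > 0 else np.nan))
    per_kmer = pd.DataFrame(
        rows, columns=["quadruplet", "n_gc", "observed", "genome_occurrences",
                       "expected", "ratio"]
    )
    present = per_kmer[per_kmer["expected"] > 0]
    chi2 = float(((present["observed"] - present["expected"]) ** 2 / present["expected"]).sum())
    dof = max(len(present) - 1, 1)
    pvalue = float(stats.chi2.sf(chi2, dof))
    rich = per_kmer[per_kmer["n_gc"] >= 3]
    exp_rich = rich["expected"].sum()
    gc_rich_ratio = float(rich["observed"].sum() / exp_rich) if exp_rich > 0 else float("nan")
    return QuadrupletBiasReport(per_kmer, gc_rich_ratio, chi2, dof, pvalue)
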