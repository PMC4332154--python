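"""Synthetic genomes, insertion libraries and expression time courses.

The generator emulates the observable structure of a mini-transposon
(HITS) essentiality experiment on a small circular bacterial genome:

* contrasting insertion densities in essential vs non-essential
  regions, with rare low-read "noise" insertions inside essential
  genes (PCR/mapping artifacts and dying clones);
* a bimodal reads-per-insertion distribution that separates an
  essential from a non-essential gold set, with negative-binomial
  overdispersion so that threshold calibration is non-trivial;
* serial-passage decay of essential-region insertion read counts
  (clones carrying them stop dividing) while non-essential counts are
  stationary in expectation;
* an optional depletion of insertions at G/C-rich quadruplets;
* expression time courses with planted correlated / anti-correlated
  ncRNA-ORF pairs, optionally biased so that anti-correlated partners
  are enriched for essential ORFs.

All ORFs are built under genetic code 4 (UGA = Trp): they start with
ATG, contain no in-frame TAA/TAG, and end with TAA or TAG. Ground
truth is carried in a :class:`~minitn.annotation.TruthAnnotation`;
fitness (F) genes are generated as mixed-domain ORFs with one
essential and one non-essential domain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FEATURE_COLUMNS, TruthAnnotation
from .calling import SITE_COLUMNS, InsertionTable, empty_provenance
from .domains import domain_to_genome
from .seq import STOPS_CODE4, circular_slice, random_sequence, revcomp


class PackingError(ValueError):
    """Requested features exceed genome capacity."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Rates are per bp per library; read counts are negative binomial
    NB1 with variance (1 + ``nb_dispersion``) * mean. ``passage_days``
    are the sampled growth days; essential-insertion read counts decay
    exponentially with half-life ``decay_halflife_days`` relative to
    the earliest day.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.40
    n_orfs: int = 120
    orf_len_range: tuple = (600, 1800)
    f_orf_len_range: tuple = (1200, 1800)
    n_smorfs: int = 15
    n_ncrnas: int = 30
    n_convrnas: int = 4
    frac_essential: float = 0.40
    frac_fitness: float = 0.08
    insertion_rate_ne: float = 0.05
    noise_rate_e: float = 5e-4
    reads_ne_mean: float = 100.0
    reads_e_mean: float = 3.0
    nb_dispersion: float = 0.5
    passage_days: tuple = (4, 8, 12)
    decay_halflife_days: float = 1.5
    quadruplet_bias: float = 1.0
    n_timepoints: int = 10
    frac_anticorrelated: float = 0.5
    plant_prob: float = 1.0
    partners_per_ncrna: float = 1.0
    p_essential_anti: float | None = None
    p_essential_corr: float | None = None
    expression_noise_sd: float = 0.3

    def validate(self) -> None:
        fracs = {
            "gc_content": self.gc_content,
            "frac_essential": self.frac_essential,
            "frac_fitness": self.frac_fitness,
            "frac_anticorrelated": self.frac_anticorrelated,
            "plant_prob": self.plant_prob,
            "quadruplet_bias": self.quadruplet_bias,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.insertion_rate_ne < 0 or self.noise_rate_e < 0:
            raise ValueError("insertion rates must be >= 0")
        if not self.reads_ne_mean > self.reads_e_mean > 0:
            raise ValueError(
                "reads_ne_mean > reads_e_mean > 0 required "
                "(calibration needs separable read-count distributions)"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.decay_halflife_days <= 0:
            raise ValueError("decay_halflife_days must be > 0")
        if self.frac_essential + self.frac_fitness > 1:
            raise ValueError("frac_essential + frac_fitness > 1")
        if len(self.passage_days) < 1:
            raise ValueError("at least one passage day required")

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["passage_days"] = list(self.passage_days)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("passage_days", "orf_len_range", "f_orf_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage
    return np.random.default_rng([config.seed, stream])


def _nb1(rng, mean, dispersion, size=None):
    """NB1 draw: variance = (1 + dispersion) * mean (size r = mean/d)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(np.broadcast_shapes(mean.shape or (1,), (size,) if size else mean.shape), dtype=np.int64)
    m = np.broadcast_to(mean, out.shape).copy()
    live = m > 1e-8
    if live.any():
        r = m[live] / dispersion
        p = r / (r + m[live])
        out[live] = rng.negative_binomial(r, p)
    return out if out.shape != () else int(out)


def _random_codons(rng, n: int, gc: float) -> str:
    """n random codons, none a code-4 stop (TAA/TAG)."""
    out: list[str] = []
    need = n
    while need > 0:
        block = random_sequence(rng, 3 * (need + 8), gc)
        for i in range(0, len(block) - 2, 3):
            cod = block[i : i + 3]
            if cod not in STOPS_CODE4:
                out.append(cod)
                need -= 1
                if need == 0:
                    break
    return "".join(out)


def _make_cds(rng, length: int, gc: float) -> str:
    """Coding sequence of ``length`` nt (multiple of 3): ATG, non-stop
    internal codons, final stop codon, all under genetic code 4."""
    assert length % 3 == 0 and length >= 9
    stop = STOPS_CODE4[rng.integers(len(STOPS_CODE4))]
    return "ATG" + _random_codons(rng, length // 3 - 2, gc) + stop


# ----------------------------------------------------------------- genome


def simulate_genome(config: SimConfig) -> tuple[str, TruthAnnotation]:
    """Generate a circular genome with ground-truth annotation.

    ORFs/smORFs/conventional RNAs are packed non-overlapping around the
    circle with random intergenic gaps; ~95% of ncRNAs are placed
    antisense inside host ORFs. Truth categories: E/NE per
    ``frac_essential``; F genes are mixed-domain ORFs (one E, one NE
    domain). One large intergenic region is marked essential (an
    oriC-like structural element); conventional RNAs are essential.
    """
    config.validate()
    rng = _rng(config, 0)
    G = config.genome_length

    n_f = int(round(config.frac_fitness * config.n_orfs))
    n_e = int(round(config.frac_essential * config.n_orfs))
    n_ne = config.n_orfs - n_e - n_f
    if n_ne < 0:
        raise ValueError("essential + fitness ORF counts exceed n_orfs")
    orf_truth = np.array(["E"] * n_e + ["NE"] * n_ne + ["F"] * n_f)
    rng.shuffle(orf_truth)

    lo, hi = config.orf_len_range
    flo, fhi = config.f_orf_len_range
    if lo < 300 or flo < 600:
        raise ValueError("ORF length ranges too short to score (min 300/600 nt)")
    orf_lens = np.where(
        orf_truth == "F",
        rng.integers(flo // 3, fhi // 3 + 1, size=config.n_orfs) * 3,
        rng.integers(lo // 3, hi // 3 + 1, size=config.n_orfs) * 3,
    )
    smorf_aas = rng.integers(25, 100, size=config.n_smorfs)  # < 100 residues
    smorf_lens = 3 * (smorf_aas + 2)  # start + aa + stop
    smorf_truth = np.where(rng.random(config.n_smorfs) < config.frac_essential, "E", "NE")
    conv_lens = rng.integers(80, 301, size=config.n_convrnas)
    n_ig_nc = int(round(0.05 * config.n_ncrnas))
    ignc_lens = rng.integers(60, 201, size=n_ig_nc)

    blocks = (
        [("ORF", int(l), t) for l, t in zip(orf_lens, orf_truth)]
        + [("smORF", int(l), t) for l, t in zip(smorf_lens, smorf_truth)]
        + [("convRNA", int(l), "E") for l in conv_lens]
        + [("ncRNA", int(l), "E" if rng.random() < 0.2 else "NE") for l in ignc_lens]
    )
    rng.shuffle(blocks)
    total = sum(l for _, l, _ in blocks)
    n_gaps = len(blocks)
    min_gap = 2
    slack = G - total - min_gap * n_gaps
    if slack < 0 or total > 0.92 * G:
        raise PackingError(
            f"requested features need {total} bp (+gaps) but genome is {G} bp"
        )
    gap_extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = gap_extra + min_gap

    genome = list(random_sequence(rng, G, config.gc_content))
    rows: list[tuple] = []
    dom_rows: list[tuple] = []
    counters = {"ORF": 0, "smORF": 0, "convRNA": 0, "ncRNA": 0}
    pos = 1 + int(gaps[0])
    orf_records = []  # (id, start, end, strand, truth) for ncRNA hosting
    for i, (ftype, length, truth) in enumerate(blocks):
        start, end = pos, pos + length - 1
        counters[ftype] += 1
        fid = f"{ftype}_{counters[ftype]:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if ftype in ("ORF", "smORF"):
            cds = _make_cds(rng, length, config.gc_content)
            seq = cds if strand == "+" else revcomp(cds)
            genome[start - 1 : end] = list(seq)
            aa_len = length // 3 - 1
            if truth == "F":
                split = int(aa_len * rng.uniform(0.35, 0.65))
                cats = ["E", "NE"] if rng.random() < 0.5 else ["NE", "E"]
                dom_rows.append((fid, f"{fid}_d1", 1, split, cats[0]))
                dom_rows.append((fid, f"{fid}_d2", split + 1, aa_len, cats[1]))
            else:
                dom_rows.append((fid, f"{fid}_d1", 1, aa_len, truth))
            if ftype == "ORF":
                orf_records.append((fid, start, end, strand, truth))
        else:
            strand = strand if ftype == "ncRNA" else "+"
        rows.append((fid, ftype, start, end, strand, truth))
        pos = end + 1 + int(gaps[(i + 1) % n_gaps]) if i + 1 < n_gaps else end + 1

    # antisense ncRNAs inside host ORFs (opposite strand)
    n_as = config.n_ncrnas - n_ig_nc
    hosts = [r for r in orf_records if r[2] - r[1] + 1 >= 160]
    rng.shuffle(hosts)
    for j in range(n_as):
        fid = f"ncRNA_{counters['ncRNA'] + 1:04d}"
        counters["ncRNA"] += 1
        hid, hs, he, hstrand, _ht = hosts[j % len(hosts)]
        length = int(rng.integers(60, min(201, he - hs - 10)))
        s = int(rng.integers(hs, he - length + 1))
        rows.append((fid, "ncRNA", s, s + length - 1, "-" if hstrand == "+" else "+", "NE"))

    # 5'-UTRs immediately upstream of a subset of ORFs, inside the gap
    feat = pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["truth"])
    occupied_ends = feat.loc[feat["type"] != "ncRNA"].sort_values("start")
    bounds = list(zip(occupied_ends["start"], occupied_ends["end"]))
    n_utr = 0
    for fid, fs, fe, strand, ftruth in orf_records:
        if rng.random() > 0.25:
            continue
        ulen = int(rng.integers(20, 61))
        if strand == "+":
            s, e = fs - ulen, fs - 1
        else:
            s, e = fe + 1, fe + ulen
        if s < 1 or e > G:
            continue
        if any(bs <= e and be >= s for bs, be in bounds if (bs, be) != (fs, fe)):
            continue
        n_utr += 1
        rows.append((f"UTR5_{n_utr:04d}", "UTR5", s, e, strand,
                     "E" if ftruth == "E" else "NE"))
        bounds.append((s, e))

    feat = pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["truth"])
    truth = TruthAnnotation(
        features=feat.reset_index(drop=True),
        G=G,
        genome_id=f"sim_{config.seed}",
        domains=pd.DataFrame(
            dom_rows, columns=["orf_id", "domain_id", "aa_start", "aa_end", "truth"]
        ),
    )
    # intergenic complement, one oriC-like essential region
    ig = truth.intergenic_regions()
    if len(ig):
        ig["truth"] = "NE"
        big = ig.index[(ig["end"] - ig["start"] + 1).ge(150)]
        if len(big):
            ig.loc[big[0], "truth"] = "E"
        truth.features = pd.concat([truth.features, ig], ignore_index=True)
    return "".join(genome), truth


def essential_mask(genome_length: int, truth: TruthAnnotation) -> np.ndarray:
    """Boolean per-base mask (index 0 = position 1) of ground-truth
    essential sequence: E features plus E domains of mixed (F) ORFs."""
    mask = np.zeros(genome_length, dtype=bool)
    for row in truth.features.itertuples():
        if row.truth == "E":
            mask[row.start - 1 : row.end] = True
    fids = set(truth.features.loc[truth.features["truth"] == "F", "id"])
    for d in truth.domains.itertuples():
        if d.truth == "E" and d.orf_id in fids:
            orf = truth.get(d.orf_id)
            s, e = domain_to_genome(d.aa_start, d.aa_end, orf["start"], orf["end"], orf["strand"])
            mask[s - 1 : e] = True
    return mask


def _gc_rich_quadruplet_mask(genome: str) -> np.ndarray:
    """True where the junction-centred 4-mer (bases p-2..p+1) has >= 3 G/C."""
    is_gc = np.frombuffer(genome.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    G = len(genome)
    idx = np.arange(G)
    total = np.zeros(G, dtype=np.int8)
    for off in (-2, -1, 0, 1):  # 0-based offsets of bases p-2..p+1 for position p=idx+1
        total += is_gc[(idx + off) % G]
    return total >= 3


def simulate_insertions(
    genome: str, truth: TruthAnnotation, config: SimConfig
) -> dict[int, InsertionTable]:
    """Simulated insertion library, one table per passage day.

    Sites are Bernoulli per position at ``insertion_rate_ne``
    (non-essential sequence) or ``noise_rate_e`` (essential sequence),
    optionally thinned by ``quadruplet_bias`` at G/C-rich quadruplets.
    Read counts are NB1 around the class mean; the essential-class mean
    decays with half-life ``decay_halflife_days`` across days. Sites
    whose read count falls to zero on a given day are absent from that
    day's table (the clone has dropped out of the library).
    """
    config.validate()
    G = len(genome)
    if G != truth.G:
        raise ValueError("annotation inconsistent with genome length")
    rng = _rng(config, 1)
    e_mask = essential_mask(G, truth)
    rate = np.where(e_mask, config.noise_rate_e, config.insertion_rate_ne)
    if config.quadruplet_bias < 1.0:
        rate = np.where(
            _gc_rich_quadruplet_mask(genome), rate * config.quadruplet_bias, rate
        )
    hit = rng.random(G) < rate
    positions = np.flatnonzero(hit) + 1
    orientation = np.where(rng.random(positions.size) < 0.5, "+", "-")
    is_e = e_mask[positions - 1]

    days = sorted(config.passage_days)
    d0 = days[0]
    out: dict[int, InsertionTable] = {}
    for d in days:
        mean_e = config.reads_e_mean * 2.0 ** (-(d - d0) / config.decay_halflife_days)
        means = np.where(is_e, mean_e, config.reads_ne_mean)
        reads = _nb1(rng, means, config.nb_dispersion)
        keep = reads >= 1
        df = pd.DataFrame(
            {
                "position": positions[keep],
                "orientation": orientation[keep],
                "reads": reads[keep],
                "sample": "sim",
                "day": d,
            }
        )[SITE_COLUMNS]
        out[d] = InsertionTable(
            df=df, G=G, genome_id=truth.genome_id, provenance=empty_provenance()
        )
    return out


def simulate_reads(
    table: InsertionTable,
    genome: str,
    ir_tag: str,
    read_length: int = 30,
) -> list[SeqRecord]:
    """FASTQ records for an insertion table: one read per (site, read
    replicate), each the IR tag followed by the genomic flank starting
    at the site coordinate on the recorded orientation (circular)."""
    G = len(genome)
    if read_length < 1 or read_length + len(ir_tag) > max(G, 10_000):
        raise ValueError("read_length + |ir_tag| exceeds practical limits")
    records: list[SeqRecord] = []
    for row in table.df.itertuples():
        p = int(row.position)
        if not 1 <= p <= G:
            raise ValueError(f"site {p} outside genome")
        if row.orientation == "+":
            flank = circular_slice(genome, p, read_length)
        else:
            flank = revcomp(circular_slice(genome, p - read_length + 1, read_length))
        seq = ir_tag + flank
        for i in range(int(row.reads)):
            rec = SeqRecord(
                Seq(seq),
                id=f"{row.sample}|d{row.day}|{p}{row.orientation}|{i}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
    return records


# ------------------------------------------------------------- expression


def antisense_pairs(truth: TruthAnnotation) -> pd.DataFrame:
    """ncRNA-ORF pairs where the ncRNA overlaps an ORF on the opposite
    strand (the candidate regulatory pairs)."""
    orfs = truth.of_type("ORF")
    rows = []
    for nc in truth.of_type("ncRNA").itertuples():
        hit = orfs[
            (orfs["start"] <= nc.end)
            & (orfs["end"] >= nc.start)
            & (orfs["strand"] != nc.strand)
        ]
        if len(hit):
            ov = np.minimum(hit["end"], nc.end) - np.maximum(hit["start"], nc.start)
            rows.append((nc.id, hit.loc[ov.idxmax(), "id"]))
    return pd.DataFrame(rows, columns=["ncrna", "orf"])


def simulate_expression(
    truth: TruthAnnotation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression time course (features x timepoints) with planted pairs.

    Each planted ncRNA gets a latent profile; its host ORF and any
    extra partners receive the exact negated (anti-correlated) or
    identical (correlated) profile, after which iid Gaussian noise at
    ``expression_noise_sd`` is added to every value. With zero noise a
    planted anti-correlated pair therefore has sample r = -1 exactly.
    Partner ORFs can be drawn preferentially from essential /
    non-essential truth via ``p_essential_anti`` / ``p_essential_corr``
    (None = unbiased). Unplanted features are mutually independent.

    Returns (matrix, planted) where ``planted`` lists
    (ncrna, orf, sign) with sign in {anti, corr}.
    """
    config.validate()
    T = config.n_timepoints
    if T < 3:
        raise ValueError("n_timepoints must be >= 3 (correlation degenerate)")
    rng = _rng(config, 3)
    feats = truth.features
    ids = list(feats.loc[feats["type"].isin(["ORF", "ncRNA"]), "id"])
    orfs = feats[feats["type"] == "ORF"]
    X = pd.DataFrame(
        rng.normal(size=(len(ids), T)),
        index=pd.Index(ids, name="feature"),
        columns=[f"t{i+1}" for i in range(T)],
    )
    pairs = antisense_pairs(truth)
    used: set[str] = set()
    e_pool = [o for o in orfs.loc[orfs["truth"] == "E", "id"]]
    ne_pool = [o for o in orfs.loc[orfs["truth"] != "E", "id"]]
    rng.shuffle(e_pool)
    rng.shuffle(ne_pool)
    planted_rows = []

    def draw_partner(p_essential):
        pools = [
            [o for o in e_pool if o not in used],
            [o for o in ne_pool if o not in used],
        ]
        if p_essential is not None and rng.random() >= p_essential:
            pools = pools[::-1]
        for pool in pools:
            if pool:
                return pool[0]
        return None

    for row in pairs.itertuples():
        if rng.random() >= config.plant_prob or row.ncrna in used:
            continue
        f = rng.normal(size=T)
        X.loc[row.ncrna] = f
        used.add(row.ncrna)
        partners = []
        if row.orf not in used:
            partners.append(row.orf)
        extra = rng.poisson(max(config.partners_per_ncrna - 1, 0))
        for sign_draw in range(len(partners), len(partners) + extra):
            partners.append(None)  # placeholder, drawn below once sign known
        for j, partner in enumerate(partners):
            anti = rng.random() < config.frac_anticorrelated
            if partner is None:
                partner = draw_partner(
                    config.p_essential_anti if anti else config.p_essential_corr
                )
                if partner is None:
                    continue
            X.loc[partner] = -f if anti else f
            used.add(partner)
            planted_rows.append((row.ncrna, partner, "anti" if anti else "corr"))

    if config.expression_noise_sd > 0:
        X += rng.normal(0, config.expression_noise_sd, size=X.shape)
    planted = pd.DataFrame(planted_rows, columns=["ncrna", "orf", "sign"])
    return X, planted
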