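"""Domain-level essentiality: project amino-acid coordinates onto the
genome and score each structural domain independently.

In many multi-domain proteins only one domain is essential; gene-level
calls then land in the fitness (F) category while the domains split
cleanly into E and NE. Domain coordinates are 1-based inclusive in
protein space; the stop codon belongs to no domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DOMAIN_COLUMNS = ["orf_id", "domain_id", "aa_start", "aa_end", "source"]


def _protein_length(orf_start: int, orf_end: int) -> int:
    nt = orf_end - orf_start + 1
    if nt % 3 != 0:
        raise ValueError(f"ORF length {nt} not divisible by 3")
    return nt // 3 - 1  # minus stop codon


def domain_to_genome(aa_start: int, aa_end: int, orf_start: int, orf_end: int,
                     strand: str) -> tuple[int, int]:
    """Genomic interval (1-based inclusive) of a protein domain."""
    if not 1 <= aa_start <= aa_end:
        raise ValueError("invalid amino-acid coordinates")
    if aa_end > _protein_length(orf_start, orf_end):
        raise ValueError(
            f"domain aa {aa_start}..{aa_end} exceeds protein length "
            f"{_protein_length(orf_start, orf_end)}"
        )
    if strand == "+":
        return orf_start + 3 * (aa_start - 1), orf_start + 3 * aa_end - 1
    return orf_end - 3 * aa_end + 1, orf_end - 3 * (aa_start - 1)


def genome_to_domain(nt_start: int, nt_end: int, orf_start: int, orf_end: int,
                     strand: str) -> tuple[int, int]:
    """Inverse of :func:`domain_to_genome` (codon-aligned intervals)."""
    if strand == "+":
        aa_start = (nt_start - orf_start) // 3 + 1
        aa_end = (nt_end - orf_start + 1) // 3
    else:
        aa_start = (orf_end - nt_end) // 3 + 1
        aa_end = (orf_end - nt_start + 1) // 3
    return aa_start, aa_end


def load_domains(source) -> pd.DataFrame:
    """Read a domain table (TSV path or DataFrame) and make each ORF's
    domains non-overlapping: overlaps are trimmed at the midpoint of
    the overlapped stretch; domains nested inside another are dropped."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    missing = [c for c in DOMAIN_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"domain table missing columns {missing}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    out = []
    for _orf, grp in df.groupby("orf_id", sort=False):
        grp = grp.sort_values(["aa_start", "aa_end"]).reset_index(drop=True)
        kept: list[pd.Series] = []
        for _, row in grp.iterrows():
            if kept and row["aa_end"] <= kept[-1]["aa_end"]:
                continue  # nested
            if kept and row["aa_start"] <= kept[-1]["aa_end"]:
                mid = (kept[-1]["aa_end"] + row["aa_start"]) // 2
                kept[-1]["aa_end"] = mid
                row = row.copy()
                row["aa_start"] = mid + 1
            kept.append(row.copy())
        out.extend(kept)
    return pd.DataFrame(out).reset_index(drop=True)


@dataclass
class DomainReport:
    calls: pd.DataFrame  # per-domain and per-linker rows
    differential: bool


def score_domains(orf, domains: pd.DataFrame, scorer) -> DomainReport:
    """Score each domain of one ORF with the genome-wide scorer.

    ``orf`` is a feature row (id/start/end/strand); ``domains`` holds
    that ORF's (non-overlapping) domains. Inter-domain linkers and
    termini are scored too and reported as unassigned intervals; the
    differential flag is computed over assigned domains only.
    """
    if len(domains) == 0:
        raise ValueError("at least one domain required")
    aa_len = _protein_length(int(orf["start"]), int(orf["end"]))
    rows = []
    covered = []
    for d in domains.sort_values("aa_start").itertuples():
        nt_s, nt_e = domain_to_genome(
            int(d.aa_start), int(d.aa_end), int(orf["start"]), int(orf["end"]), orf["strand"]
        )
        call = scorer.score(nt_s, nt_e, d.domain_id)
        rows.append(
            (orf["id"], d.domain_id, int(d.aa_start), int(d.aa_end), nt_s, nt_e,
             call.P_E, call.P_NE, call.category, call.n_insertions, call.longest_gap, True)
        )
        covered.append((int(d.aa_start), int(d.aa_end)))
    # linkers / termini
    gaps, prev = [], 0
    for s, e in covered:
        if s > prev + 1:
            gaps.append((prev + 1, s - 1))
        prev = max(prev, e)
    if prev < aa_len:
        gaps.append((prev + 1, aa_len))
    for i, (s, e) in enumerate(gaps, 1):
        nt_s, nt_e = domain_to_genome(s, e, int(orf["start"]), int(orf["end"]), orf["strand"])
        call = scorer.score(nt_s, nt_e, f"{orf['id']}_linker{i}")
        rows.append(
            (orf["id"], f"linker_{i}", s, e, nt_s, nt_e,
             call.P_E, call.P_NE, call.category, call.n_insertions, call.longest_gap, False)
        )
    calls = pd.DataFrame(
        rows,
        columns=["orf_id", "domain_id", "aa_start", "aa_end", "nt_start", "nt_end",
                 "P_E", "P_NE", "category", "n_insertions", "longest_gap", "assigned"],
    )
    assigned = calls[calls["assigned"]]
    differential = assigned["category"].nunique() >= 2
    return DomainReport(calls=calls, differential=differential)


def score_all_domains(annotation, domains: pd.DataFrame, scorer) -> pd.DataFrame:
    """Domain calls for every ORF in the table, plus a per-ORF
    ``differential`` column."""
    frames = []
    feats = annotation.features.set_index("id")
    for orf_id, grp in domains.groupby("orf_id", sort=False):
        if orf_id not in feats.index:
            raise KeyError(f"domain ORF {orf_id!r} absent from annotation")
        orf = feats.loc[orf_id]
        orf = pd.Series({**orf.to_dict(), "id": orf_id})
        rep = score_domains(orf, grp, scorer)
        rep.calls["differential"] = rep.differential
        frames.append(rep.calls)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
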