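"""Genome annotation container.

Features live in a pandas DataFrame with columns
``id, type, start, end, strand`` (1-based inclusive coordinates,
strand '+'/'-') plus optional extra columns such as ``truth`` (the
simulator's ground-truth essentiality category). Feature types follow
the vocabulary used throughout the package: ``ORF``, ``smORF``,
``ncRNA``, ``UTR5``, ``convRNA``, ``intergenic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_TYPES = ("ORF", "smORF", "ncRNA", "UTR5", "convRNA", "intergenic")

#: feature classes whose complement defines intergenic space
_GENIC_TYPES = ("ORF", "smORF", "ncRNA", "UTR5", "convRNA")

FEATURE_COLUMNS = ["id", "type", "start", "end", "strand"]


@dataclass
class GenomeAnnotation:
    """Typed features on a (circular) genome of length ``G``."""

    features: pd.DataFrame
    G: int
    genome_id: str = "genome"
    circular: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        f = self.features
        if len(f) and ((f["start"] < 1).any() or (f["end"] > self.G).any()):
            raise ValueError("feature coordinates outside [1, G]")
        if len(f) and (f["start"] > f["end"]).any():
            raise ValueError("feature with start > end (wrapping features unsupported)")
        if f["id"].duplicated().any():
            dup = f.loc[f["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate feature id {dup!r}")

    def of_type(self, ftype: str) -> pd.DataFrame:
        if ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature class {ftype!r}")
        return self.features[self.features["type"] == ftype]

    def get(self, feature_id: str) -> pd.Series:
        rows = self.features[self.features["id"] == feature_id]
        if not len(rows):
            raise KeyError(feature_id)
        return rows.iloc[0]

    def intergenic_regions(self, min_length: int = 1) -> pd.DataFrame:
        """Complement of all genic features on the circular genome.

        Explicit ``intergenic`` features, if present, are returned as-is;
        otherwise the complement is computed. Returns a features-shaped
        frame (strand '.').
        """
        explicit = self.features[self.features["type"] == "intergenic"]
        if len(explicit):
            out = explicit[explicit["end"] - explicit["start"] + 1 >= min_length]
            return out.reset_index(drop=True)
        genic = self.features[self.features["type"].isin(_GENIC_TYPES)]
        covered = np.zeros(self.G + 1, dtype=bool)  # index 1..G
        for s, e in zip(genic["start"], genic["end"]):
            covered[s : e + 1] = True
        free = ~covered[1:]
        # runs of uncovered bases
        edges = np.flatnonzero(np.diff(np.concatenate(([0], free.view(np.int8), [0]))))
        starts, ends = edges[::2] + 1, edges[1::2]
        rows = []
        for i, (s, e) in enumerate(zip(starts, ends)):
            if e - s + 1 >= min_length:
                rows.append((f"IG_{i+1:04d}", "intergenic", int(s), int(e), "."))
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


@dataclass
class TruthAnnotation(GenomeAnnotation):
    """Annotation carrying simulator ground truth.

    ``features`` gains a ``truth`` column (E/NE/F per feature);
    ``domains`` holds per-ORF domain truth with 1-based inclusive
    amino-acid coordinates.
    """

    domains: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["orf_id", "domain_id", "aa_start", "aa_end", "truth"]
        )
    )

    def __post_init__(self) -> None:
        super().__post_init__()
        if "truth" not in self.features.columns:
            raise ValueError("truth annotation requires a 'truth' column")
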