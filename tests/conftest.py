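import numpy as np
import pandas as pd
import pytest

from minitn import (
    EssentialityClassifier,
    GoldSet,
    SimConfig,
    select_timepoint,
    simulate_genome,
    simulate_insertions,
)


def gold_from_truth(truth, n_e=37, n_ne=29):
    orfs = truth.of_type("ORF")
    return GoldSet(
        list(orfs.loc[orfs["truth"] == "E", "id"][:n_e]),
        list(orfs.loc[orfs["truth"] == "NE", "id"][:n_ne]),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small but well-separated simulated experiment, reused read-only."""
    cfg = SimConfig(seed=11, genome_length=60_000, n_orfs=40, n_smorfs=6, n_ncrnas=12)
    genome, truth = simulate_genome(cfg)
    tables = simulate_insertions(genome, truth, cfg)
    return cfg, genome, truth, tables


@pytest.fixture(scope="session")
def fitted_classifier(small_sim):
    cfg, genome, truth, tables = small_sim
    gold = gold_from_truth(truth, n_e=10, n_ne=10)
    day, _ = select_timepoint(tables, gold, truth)
    clf = EssentialityClassifier(read_threshold="stringent").fit(
        tables[day], annotation=truth, gold=gold
    )
    return clf, tables[day], gold


def make_table(positions, G, reads=None, orientations=None, sample="s", day=0,
               genome_id="toy"):
    """Insertion table from explicit positions (test helper)."""
    from minitn.calling import SITE_COLUMNS, InsertionTable, empty_provenance

    positions = list(positions)
    n = len(positions)
    df = pd.DataFrame(
        {
            "position": positions,
            "orientation": orientations or ["+"] * n,
            "reads": reads if reads is not None else [1] * n,
            "sample": sample,
            "day": day,
        }
    )[SITE_COLUMNS]
    return InsertionTable(df=df, G=G, genome_id=genome_id, provenance=empty_provenance())


def brute_force_call(positions, G, alpha, w, N, start, end):
    """Independent per-base labeling oracle for region scoring.

    Labels every base of the circular genome: E-evidence if it lies in
    a maximal insertion-free run whose gap-null probability is <= alpha;
    NE-evidence (for the region) if within w of a site inside the
    region. Averages over the region with half-up rounding.
    """
    from minitn.scoring import classify_call, gap_null_probability, round2

    occupied = np.zeros(G + 1, dtype=bool)
    for p in positions:
        occupied[p] = True
    # maximal insertion-free circular runs, per-base significance label
    e_label = np.zeros(G + 1, dtype=bool)
    free = ~occupied[1:]
    if free.all():
        raise ValueError("no sites")
    # rotate so index 0 is a site; runs never wrap after rotation
    first_site = int(np.flatnonzero(~free)[0])
    rot = np.roll(free, -first_site)
    runs = []
    i = 0
    while i < G:
        if rot[i]:
            j = i
            while j < G and rot[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    for a, b in runs:
        L = b - a + 1
        if gap_null_probability(L, N, G) <= alpha:
            for k in range(a, b + 1):
                e_label[(k + first_site) % G + 1] = True
    region = list(range(start, end + 1))
    inside_sites = [p for p in positions if start <= p <= end]
    ne_label = set()
    for p in inside_sites:
        for b in range(max(p - w, start), min(p + w, end) + 1):
            ne_label.add(b)
    n_e = sum(e_label[b] for b in region)
    P_E = round2(n_e, len(region))
    P_NE = round2(len(ne_label), len(region))
    return P_E, P_NE, classify_call(P_E, P_NE)
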