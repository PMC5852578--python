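"""miRNA quantification, fold changes, 4-group classification and satellites."""

import numpy as np
import pandas as pd
import pytest

import srnafrac as sf
from srnafrac import preprocess as preprocess_mod
from srnafrac.mirna import (
    FC_COLUMNS,
    PSEUDOCOUNT,
    abundance_panel,
    classify_groups,
    cluster_cosedimentation,
    editing_candidates,
    filter_low,
    fold_change,
    fraction_distribution,
    hairpin_shares,
    load_polysome_table,
    quantify,
)

SAMPLES = [f"{s}_{f}" for s in ("0-1h", "7-8h") for f in ("UF", "mRNP", "60S", "80S", "Poly")]


def _records(seq_counts: dict[str, int], sample: str = "0-1h_UF") -> pd.DataFrame:
    df = pd.DataFrame(0, index=pd.Index(list(seq_counts), name="sequence"),
                      columns=SAMPLES)
    for seq, n in seq_counts.items():
        df.loc[seq, sample] = n
    return df


def test_quantify_exact_window_and_mismatch(ref):
    m = ref.mature_mirnas.iloc[0]
    hp = ref.categories["miRNA"][m["hairpin"]]
    mature = m["sequence"]
    shifted = hp[m["start"] + 2:m["start"] + 2 + len(mature)]
    mutated = ("A" if mature[4] != "A" else "G").join([mature[:4], mature[5:]])
    records = _records({mature: 3, shifted: 2, mutated: 5})
    denom = pd.Series(1e6, index=SAMPLES)
    matrix = quantify(records, None, ref, denominators=denom)
    assert matrix.counts.loc[m["name"], "0-1h_UF"] == 5      # exact + shifted
    assert matrix.rpm.loc[m["name"], "0-1h_UF"] == 5.0       # RPM at denom 1e6
    assert matrix.counts.values.sum() == 5                   # mutated not counted


def test_quantify_rejects_bad_mature(ref):
    broken = ref.mature_mirnas.copy()
    broken.loc[0, "sequence"] = "A" * 22
    bad = sf.ReferenceSet(
        categories=ref.categories, mature_mirnas=broken,
        pirna_clusters=ref.pirna_clusters, genome=ref.genome,
        repeat_families=ref.repeat_families, trnas_cca=ref.trnas_cca,
    )
    with pytest.raises(ValueError, match="not contained"):
        quantify(_records({"ACGT" * 5: 1}), None, bad,
                 denominators=pd.Series(1.0, index=SAMPLES))


def test_filter_low_threshold_inclusive():
    rpm = pd.DataFrame({"s": [49.9, 50.0, 300.0]}, index=["a", "b", "c"])
    kept = filter_low(rpm)
    assert list(kept.index) == ["b", "c"]


@pytest.mark.parametrize(
    "early, late, expected",
    [(0.0, 0.0, 0.0), (10.0, 30.0, 1.0)],
)
def test_fold_change_arithmetic(early, late, expected):
    rpm = pd.DataFrame({c: [0.0] for c in SAMPLES}, index=["m"])
    rpm["0-1h_UF"] = early
    rpm["7-8h_UF"] = late
    fc = fold_change(rpm)
    assert fc.loc["m", "Tot"] == pytest.approx(expected)


def test_fold_change_bounded_by_pseudocount():
    rpm = pd.DataFrame({c: [0.0] for c in SAMPLES}, index=["m"])
    rpm["7-8h_UF"] = 1e6
    fc = fold_change(rpm)
    bound = np.log2((1e6 + PSEUDOCOUNT) / PSEUDOCOUNT)
    assert abs(fc.loc["m", "Tot"]) <= bound


def test_fold_change_rejects_negative():
    rpm = pd.DataFrame({c: [-1.0] for c in SAMPLES}, index=["m"])
    with pytest.raises(ValueError, match="negative"):
        fold_change(rpm)


@pytest.mark.parametrize(
    "name, row, expected",
    [
        ("dme-miR-286-3p", (2.6, 3.1, 2.2, 2.1, 1.6), "G1"),
        ("dme-miR-9a-5p", (0.8, 0.5, 1.9, 1.5, 3.3), "G2"),
        ("dme-miR-306-5p", (-5.1, -5.2, -0.6, -0.8, -1.1), "G3"),
        ("dme-miR-1-3p", (-1.5, 0.2, 2.2, 1.2, 3.8), "G4"),
        ("dme-miR-981-3p", (1.0, -1.9, -0.1, 0.6, 0.4), "G4"),
    ],
)
def test_classify_published_examples(name, row, expected):
    fc = pd.DataFrame([row], columns=list(FC_COLUMNS), index=[name])
    assert classify_groups(fc)[name] == expected


def test_classify_requires_all_columns():
    fc = pd.DataFrame({"Tot": [1.0]})
    with pytest.raises(ValueError, match="missing"):
        classify_groups(fc)


def test_groups_partition_published_table():
    table = load_polysome_table()
    groups = classify_groups(table[list(FC_COLUMNS)])
    assert groups.value_counts().sum() == len(table)
    assert set(groups) <= {"G1", "G2", "G3", "G4"}


def test_abundance_panel_union_bounds():
    idx = [f"h{i}" for i in range(30)]
    shared = pd.DataFrame(
        {s: np.linspace(30, 0.1, 30) for s in ("a", "b")}, index=idx
    )
    panel, coverage = abundance_panel(shared, k=10)
    assert len(panel) == 10                       # identical top-10: lower bound
    disjoint = pd.DataFrame(0.1, index=idx[:20], columns=["a", "b"])
    disjoint.loc[idx[:10], "a"] = 10.0
    disjoint.loc[idx[10:20], "b"] = 10.0
    panel2, _ = abundance_panel(disjoint, k=10)
    assert len(panel2) == 20                      # disjoint top-10: upper bound
    with pytest.raises(ValueError):
        abundance_panel(shared, k=0)


def test_abundance_panel_recovers_designed_set():
    """The top-10 union equals the high-share hairpin set of a designed library."""
    rng = np.random.default_rng(3)
    idx = [f"h{i}" for i in range(30)]
    designed = set(idx[:10])
    shares = pd.DataFrame(index=idx, columns=[f"s{j}" for j in range(10)], dtype=float)
    for col in shares.columns:
        high = rng.uniform(5, 10, 10)
        low = rng.uniform(0.01, 0.5, 20)
        vals = np.concatenate([high, low])
        shares[col] = 100 * vals / vals.sum()
    panel, coverage = abundance_panel(shares, k=10)
    assert set(panel.index) == designed
    assert (coverage > 80).all()


def test_fraction_distribution_rows_sum_to_100():
    rpm = pd.DataFrame({c: [10.0, 0.0] for c in SAMPLES}, index=["even", "zero"])
    for c in SAMPLES:
        rpm.loc["zero", c] = 0.0
    dist = fraction_distribution(rpm)
    row = dist.loc["even", "0-1h"]
    assert np.allclose(row.values, 25.0)
    assert ("zero", "0-1h") in dist.attrs["undefined"]
    only = pd.DataFrame({c: [0.0] for c in SAMPLES}, index=["m"])
    only["0-1h_mRNP"] = 40.0
    d2 = fraction_distribution(only)
    assert d2.loc["m", ("0-1h", "mRNP")] == 100.0
    assert d2.loc["m", ("0-1h", "Poly")] == 0.0


def test_cosedimentation_distances_and_separation():
    vecs = pd.DataFrame(
        [[100.0, 0.0, 0.0, 0.0],
         [100.0, 0.0, 0.0, 0.0],
         [0.0, 100.0, 0.0, 0.0],
         [0.0, 100.0, 0.0, 0.0]],
        index=["m1", "m2", "m3", "m4"],
        columns=["mRNP", "60S", "80S", "Poly"],
    )
    clusters = pd.Series({"m1": "c1", "m2": "c1", "m3": "c2", "m4": "c2"})
    rep = cluster_cosedimentation(vecs, clusters)
    assert rep.distances.loc["m1", "m2"] == 0.0
    assert rep.distances.loc["m1", "m3"] == pytest.approx(100 * np.sqrt(2))
    assert rep.within_mean < rep.between_mean
    assert rep.separation < 0
    assert not rep.undefined
    assert rep.newick.endswith(";")


def test_cosedimentation_singletons_flagged():
    vecs = pd.DataFrame(
        [[100.0, 0.0], [0.0, 100.0]], index=["m1", "m2"], columns=["a", "b"]
    )
    rep = cluster_cosedimentation(vecs, pd.Series({"m1": "c1", "m2": "c2"}))
    assert rep.undefined


def test_editing_candidate_detection(ref):
    m = ref.mature_mirnas.iloc[0]
    mature = m["sequence"]
    pos = 11
    alt = "T" if mature[pos - 1] != "T" else "G"
    variant = mature[:pos - 1] + alt + mature[pos:]
    records = _records({mature: 70, variant: 30})
    out = editing_candidates(records, ref)
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["miRNA"], row["position"], row["ref"], row["alt"]) == (
        m["name"], pos, mature[pos - 1], alt
    )
    assert row["fraction"] == pytest.approx(0.3)
    # below support thresholds: no candidate
    weak = _records({mature: 10000, variant: 5})
    assert editing_candidates(weak, ref).empty
    # no mismatched reads at all
    assert editing_candidates(_records({mature: 50}), ref).empty


def test_editing_candidate_through_pipeline(ref):
    """A planted 30% C->T-style variant at position 11 survives the pipeline."""
    target = None
    for _, m in ref.mature_mirnas.iterrows():
        if m["sequence"][10] == "C":
            target = m
            break
    assert target is not None
    cfg = sf.SimulationConfig(
        seed=17,
        samples=(("0-1h", "UF"),),
        reads_per_sample=4000,
        composition={("0-1h", "UF"): {"mirna": 1.0}},
        planted_variants=((target["name"], 11, "C", "T", 0.3),),
    )
    reads, _ = sf.simulate_library(ref, cfg)
    records, _ = preprocess_mod.run_preprocess(reads, cfg.barcode_map, cfg.adapter)
    out = editing_candidates(records, ref)
    hits = out[(out["miRNA"] == target["name"]) & (out["position"] == 11)]
    assert len(hits) == 1
    assert hits.iloc[0]["ref"] == "C" and hits.iloc[0]["alt"] == "T"
    assert 0.15 <= hits.iloc[0]["fraction"] <= 0.45


def test_rpm_conservation_and_hairpin_shares(prep, assignments, ref):
    records, _ = prep
    matrix = quantify(records, assignments, ref)
    lhs = matrix.counts.sum(axis=0) * 1e6 / matrix.denominators
    assert np.allclose(lhs, matrix.rpm.sum(axis=0))
    shares = hairpin_shares(matrix)
    sums = shares.sum(axis=0)
    assert np.allclose(sums[sums > 0], 100.0)
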