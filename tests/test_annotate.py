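"""Hierarchical category assignment, QC tiers, remapping and composition."""

import numpy as np
import pandas as pd
import pytest

from srnafrac.annotate import (
    assign_category,
    composition,
    locate_in_clusters,
    qc_align,
    remap_special,
)
from srnafrac.config import SIM_CATEGORY_TO_ANNOT
from srnafrac.simulate import CATEGORY_ORDER, ClusterCopy, ReferenceSet, revcomp


def _records(seqs: list[str], sample: str = "s1") -> pd.DataFrame:
    df = pd.DataFrame({sample: [1] * len(seqs)}, index=pd.Index(seqs, name="sequence"))
    return df


@pytest.fixture(scope="module")
def toy():
    """Tiny hand-layout reference with a 20-mer shared by rRNA and transposon."""
    rng = np.random.default_rng(99)
    rand = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    shared = rand(20)
    cats = {cat: {f"{cat}-1": rand(60)} for cat in CATEGORY_ORDER}
    cats["rRNA"]["rRNA-1"] = rand(20) + shared + rand(20)
    cats["transposon"]["transposon-1"] = rand(20) + shared + rand(20)
    hp = rand(90)
    cats["miRNA"]["miRNA-1"] = hp
    mature = pd.DataFrame([{
        "name": "mir-1", "hairpin": "miRNA-1", "start": 15, "end": 37,
        "sequence": hp[15:37], "cluster": "mc-1",
    }])
    trnas = {"tRNA-1": cats["tRNA"]["tRNA-1"] + "CCA"}
    cats["tRNA"] = trnas
    cluster_seq = cats["transposon"]["transposon-1"] + cats["intergenic"]["intergenic-1"]
    chr2 = rand(30) + cluster_seq + rand(30)
    genome = {
        "chr1": rand(20) + "".join(s for c in cats.values() for s in c.values()) + rand(20),
        "chr2": chr2,
    }
    ref = ReferenceSet(
        categories=cats,
        mature_mirnas=mature,
        pirna_clusters=pd.DataFrame(
            [{"contig": "chr2", "start": 30, "end": 30 + len(cluster_seq), "name": "cl-1"}]
        ),
        genome=genome,
        repeat_families={"repfam-1": cats["transposon"]["transposon-1"]},
        trnas_cca=trnas,
        cluster_copies=[],
    )
    ref.validate()
    return ref, shared


def _brute_min_subs(seq: str, targets: list[str]) -> int:
    best = len(seq)
    for t in targets:
        for strand_seq in (t, revcomp(t)):
            for i in range(len(strand_seq) - len(seq) + 1):
                mm = sum(a != b for a, b in zip(seq, strand_seq[i:i + len(seq)]))
                best = min(best, mm)
    return best


def _all_toy_seqs(ref) -> list[str]:
    return [s for c in ref.categories.values() for s in c.values()]


def test_priority_order_rrna_wins(toy):
    ref, shared = toy
    out = assign_category(_records([shared]), ref)
    assert out.loc[shared, "category"] == "rRNA"
    assert out.loc[shared, "tier"] == 0
    assert out.loc[shared, "multiplicity"] >= 2   # hits in rRNA and transposon


def test_hairpin_one_substitution_is_tier1(toy):
    ref, _ = toy
    hp = ref.categories["miRNA"]["miRNA-1"]
    seq = hp[10:32]
    mutated = ("A" if seq[5] != "A" else "G").join([seq[:5], seq[6:]])
    assert _brute_min_subs(mutated, _all_toy_seqs(ref)) == 1
    out = assign_category(_records([mutated]), ref)
    assert out.loc[mutated, "category"] == "miRNA"
    assert out.loc[mutated, "tier"] == 1


def test_two_substitutions_assigned_at_tier2(toy):
    ref, _ = toy
    seq = ref.categories["transcript"]["transcript-1"][5:27]
    mut = list(seq)
    for i in (3, 15):
        mut[i] = "A" if mut[i] != "A" else "G"
    mut = "".join(mut)
    if _brute_min_subs(mut, _all_toy_seqs(ref)) == 2:
        out = assign_category(_records([mut]), ref)
        assert out.loc[mut, "category"] == "transcript"
        assert out.loc[mut, "tier"] == 2


def test_unmatched_insert_is_unassigned(toy):
    ref, _ = toy
    rng = np.random.default_rng(123)
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=25))
        if _brute_min_subs(seq, _all_toy_seqs(ref)) > 3:
            break
    out = assign_category(_records([seq]), ref)
    assert out.loc[seq, "category"] == "unassigned"
    assert out.loc[seq, "tier"] == -1


def test_antisense_match_recorded(toy):
    ref, _ = toy
    sub = ref.categories["transposon"]["transposon-1"][10:31]
    anti = revcomp(sub)
    out = assign_category(_records([anti]), ref)
    assert out.loc[anti, "category"] == "transposon"
    assert out.loc[anti, "strand"] == "antisense"


def test_qc_tiers(toy):
    ref, _ = toy
    genome_sub = ref.genome["chr1"][40:65]
    deleted = genome_sub[:10] + genome_sub[11:]       # one deletion
    rng = np.random.default_rng(5)
    while True:
        random25 = "".join(rng.choice(list("ACGT"), size=25))
        targets = list(ref.genome.values()) + list(ref.trnas_cca.values())
        if _brute_min_subs(random25, targets) > 3:
            break
    records = _records([genome_sub, deleted, random25])
    report = qc_align(records, ref)
    assert report.loc["exact", "s1"] == 1
    assert report.loc["one_edit", "s1"] == 1
    assert report.loc["unmapped", "s1"] == 1
    assert report["s1"].sum() == len(records)


def test_qc_requires_reference(toy):
    ref, _ = toy
    empty = ReferenceSet(
        categories=ref.categories, mature_mirnas=ref.mature_mirnas,
        pirna_clusters=ref.pirna_clusters, genome={}, repeat_families={},
        trnas_cca={},
    )
    with pytest.raises(ValueError, match="empty"):
        qc_align(_records(["ACGT" * 5]), empty)


def test_remap_family_and_cluster(toy):
    ref, _ = toy
    tn = ref.categories["transposon"]["transposon-1"][5:26]
    ig = ref.categories["intergenic"]["intergenic-1"][10:30]
    mut = ("A" if tn[8] != "A" else "G").join([tn[:8], tn[9:]])
    records = _records([tn, ig, mut])
    assignments = assign_category(records, ref)
    refined = remap_special(assignments, ref)
    assert refined.loc[tn, "family"] == "repfam-1"
    assert refined.loc[tn, "in_cluster"]
    assert refined.loc[ig, "category"] == "intergenic"
    assert refined.loc[ig, "in_cluster"] and refined.loc[ig, "cluster"] == "cl-1"
    # 1-mismatch consensus variant: assigned transposon but exact-only remap fails
    assert refined.loc[mut, "category"] == "transposon"
    assert refined.loc[mut, "family"] == ""


def test_locate_in_clusters_reports_strand(toy):
    ref, _ = toy
    sub = ref.categories["transposon"]["transposon-1"][5:26]
    hits = locate_in_clusters([sub, revcomp(sub)], ref)
    strands = hits.groupby("sequence")["strand"].first()
    assert strands[sub] == "+" and strands[revcomp(sub)] == "-"


def test_composition_degenerate_and_normalised(toy):
    ref, _ = toy
    r = ref.categories["rRNA"]["rRNA-1"][0:20]
    t = ref.categories["transcript"]["transcript-1"][0:20]
    records = pd.DataFrame(
        {"s1": [5, 0], "s2": [2, 2]},
        index=pd.Index([r, t], name="sequence"),
    )
    table = composition(assign_category(records, ref), records)
    assert table.loc["rRNA", "s1"] == 100.0
    assert abs(table["s1"].sum() - 100.0) < 1e-9
    assert abs(table["s2"].sum() - 100.0) < 1e-9
    assert table.loc["rRNA", "s2"] == 50.0


def test_partition_every_insert_exactly_once(assignments):
    assert assignments["category"].notna().all()
    assert set(assignments["category"]) <= set(CATEGORY_ORDER) | {"unassigned"}
    assert len(assignments) == assignments.index.nunique()


def test_tier_monotonicity(assignments):
    """Fraction assigned by allowed tier t never decreases with t."""
    fractions = [
        (assignments["tier"].between(0, t)).mean() for t in range(4)
    ]
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))


def test_category_recovery_on_synthetic_library(assignments, gt_insert_category):
    """>=99% of inserts recover their ground-truth category at tier 0."""
    common = assignments.index.intersection(gt_insert_category.index)
    assert len(common) > 5000
    sub = assignments.loc[common]
    correct = (sub["category"] == gt_insert_category.loc[common]) & (sub["tier"] == 0)
    assert correct.mean() >= 0.99


def test_composition_recovery_within_two_points(ref, comp_library):
    """Annotated composition matches the configured mixture to +-2 points
    at 10,000 reads per sample."""
    comp_cfg, records = comp_library
    assignments = assign_category(records, ref)
    table = composition(assignments, records)
    for (stage, fraction), comp in comp_cfg.composition.items():
        if (stage, fraction) not in comp_cfg.samples:
            continue
        sid = f"{stage}_{fraction}"
        expected: dict[str, float] = {}
        for sim_cat, p in comp.items():
            annot = SIM_CATEGORY_TO_ANNOT[sim_cat]
            expected[annot] = expected.get(annot, 0.0) + 100.0 * p
        for annot, pct in expected.items():
            assert abs(table.loc[annot, sid] - pct) <= 2.0, (sid, annot)
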