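"""Hierarchical annotation of collapsed small-RNA inserts.

Each insert is assigned to exactly one reference category by a tier-major
sweep: all ten categories are tried for exact (tier-0) matches in priority
order (rRNA, miRNA hairpin, tRNA, miscRNA, ncRNA, transposon, transcript,
intron, pseudogene, intergenic) before any mismatch tier is opened, so a
3-mismatch rRNA hit can never pre-empt an exact miRNA hit.  A "match" is an
end-to-end alignment of the insert inside a reference sequence with at most
t substitutions, on either strand.  Quality control against the genome (plus
CCA-appended mature tRNAs) uses a separate tier ladder whose 1-error tier
also admits a single insertion or deletion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

import edlib

from .simulate import CATEGORY_ORDER, ReferenceSet, revcomp

MAX_TIER = 3

QC_TIERS = ("exact", "one_edit", "two_mismatches", "three_mismatches", "unmapped")


def _count_occurrences(hay: str, needle: str) -> int:
    n, i = 0, hay.find(needle)
    while i != -1:
        n += 1
        i = hay.find(needle, i + 1)
    return n


class _StrandIndex:
    """Concatenated reference haystack with exact and Hamming-window search."""

    def __init__(self, seqs: list[str]):
        sep = "####"
        self.hay = sep.join(seqs) if seqs else ""
        self.arr = np.frombuffer(self.hay.encode(), dtype=np.uint8)
        self.sep_mask = self.arr == ord("#")

    def exact_count(self, seq: str) -> int:
        return _count_occurrences(self.hay, seq)

    def mm_counts(self, seq: str, max_mm: int = MAX_TIER) -> np.ndarray:
        """Number of end-to-end alignment windows at each mismatch count 0..max_mm."""
        L = len(seq)
        out = np.zeros(max_mm + 1, dtype=int)
        if L == 0 or len(self.arr) < L:
            return out
        windows = sliding_window_view(self.arr, L)
        ins = np.frombuffer(seq.encode(), dtype=np.uint8)
        mm = (windows != ins).sum(axis=1)
        crossing = sliding_window_view(self.sep_mask, L).any(axis=1)
        mm = mm[~crossing]
        for t in range(max_mm + 1):
            out[t] = int((mm == t).sum())
        return out


class _CategoryIndex:
    def __init__(self, seqs: dict[str, str]):
        self.sense = _StrandIndex(list(seqs.values()))
        self.anti = _StrandIndex([revcomp(s) for s in seqs.values()])

    def exact(self, seq: str) -> tuple[int, int]:
        return self.sense.exact_count(seq), self.anti.exact_count(seq)

    def mm(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        return self.sense.mm_counts(seq), self.anti.mm_counts(seq)


def assign_category(records: pd.DataFrame, ref: ReferenceSet) -> pd.DataFrame:
    """Assign every insert to one category (or ``unassigned``).

    ``records`` is the collapsed insert table (indexed by sequence).  Returns
    a DataFrame indexed by sequence with columns ``category``, ``tier``
    (smallest mismatch count achieving a hit; -1 when unassigned), ``strand``
    (``sense``/``antisense``; sense wins ties) and ``multiplicity`` (number
    of reference hits at the winning tier across all categories and both
    strands — the mapping-site count used for spectrum normalisation).
    """
    for cat in CATEGORY_ORDER:
        if cat not in ref.categories:
            raise ValueError(f"reference lacks category {cat!r}")
    indexes = {cat: _CategoryIndex(ref.categories[cat]) for cat in CATEGORY_ORDER}
    seqs = list(records.index)
    result: dict[str, tuple[str, int, str, int]] = {}

    # tier 0: exact substring, categories in priority order
    unassigned = []
    for seq in seqs:
        winner, strand, total = None, "", 0
        for cat in CATEGORY_ORDER:
            ns, na = indexes[cat].exact(seq)
            if (ns or na) and winner is None:
                winner, strand = cat, "sense" if ns else "antisense"
            total += ns + na
        if winner is not None:
            result[seq] = (winner, 0, strand, total)
        else:
            unassigned.append(seq)

    # mismatch tiers: cache full mismatch profiles, then sweep tiers 1..3
    profiles = {
        seq: {cat: indexes[cat].mm(seq) for cat in CATEGORY_ORDER}
        for seq in unassigned
    }
    for tier in range(1, MAX_TIER + 1):
        still = []
        for seq in unassigned:
            winner, strand, total = None, "", 0
            for cat in CATEGORY_ORDER:
                s_cnt, a_cnt = profiles[seq][cat]
                ns, na = int(s_cnt[:tier + 1].sum()), int(a_cnt[:tier + 1].sum())
                if (ns or na) and winner is None:
                    winner, strand = cat, "sense" if ns else "antisense"
                total += ns + na
            if winner is not None:
                result[seq] = (winner, tier, strand, total)
            else:
                still.append(seq)
        unassigned = still
    for seq in unassigned:
        result[seq] = ("unassigned", -1, "", 0)

    out = pd.DataFrame(
        [result[s] for s in seqs],
        index=pd.Index(seqs, name="sequence"),
        columns=["category", "tier", "strand", "multiplicity"],
    )
    return out


def qc_align(records: pd.DataFrame, ref: ReferenceSet) -> pd.DataFrame:
    """Tiered genome alignment report (exact / 1 edit / 2 mm / 3 mm / unmapped).

    Targets are the genome contigs plus CCA-appended mature tRNAs; both
    strands are searched.  The 1-error tier admits a substitution, insertion
    or deletion; the 2- and 3-error tiers are substitution-only.  Counts are
    read-weighted per sample.
    """
    targets = list(ref.genome.values()) + list(ref.trnas_cca.values())
    if not targets:
        raise ValueError("empty QC reference")
    both = targets + [revcomp(t) for t in targets]
    exact_index = _StrandIndex(both)

    tiers: dict[str, str] = {}
    for seq in records.index:
        if exact_index.exact_count(seq) > 0:
            tiers[seq] = "exact"
            continue
        one = any(
            edlib.align(seq, t, mode="HW", task="distance", k=1)["editDistance"] >= 0
            for t in both
        )
        if one:
            tiers[seq] = "one_edit"
            continue
        counts = exact_index.mm_counts(seq)
        if counts[:3].sum() > 0:
            tiers[seq] = "two_mismatches"
        elif counts.sum() > 0:
            tiers[seq] = "three_mismatches"
        else:
            tiers[seq] = "unmapped"

    tier_series = pd.Series(tiers, name="qc_tier")
    report = pd.DataFrame(0, index=list(QC_TIERS), columns=records.columns, dtype=int)
    for seq, tier in tier_series.items():
        report.loc[tier] += records.loc[seq]
    assert (report.sum(axis=0) == records.sum(axis=0)).all()
    return report


def locate_in_clusters(seqs: list[str], ref: ReferenceSet) -> pd.DataFrame:
    """All exact genomic placements of ``seqs`` inside piRNA cluster intervals.

    Returns one row per hit: sequence, contig, start, end (0-based
    half-open), strand (+/-), five_prime (genomic coordinate of the 5' end)
    and cluster name.
    """
    rows = []
    for _, cl in ref.pirna_clusters.iterrows():
        region = ref.genome[cl["contig"]][cl["start"]:cl["end"]]
        for seq in seqs:
            for strand in ("+", "-"):
                needle = seq if strand == "+" else revcomp(seq)
                i = region.find(needle)
                while i != -1:
                    start = cl["start"] + i
                    end = start + len(seq)
                    rows.append({
                        "sequence": seq, "contig": cl["contig"],
                        "start": start, "end": end, "strand": strand,
                        "five_prime": start if strand == "+" else end - 1,
                        "cluster": cl["name"],
                    })
                    i = region.find(needle, i + 1)
    return pd.DataFrame(
        rows,
        columns=["sequence", "contig", "start", "end", "strand", "five_prime", "cluster"],
    )


def remap_special(assignments: pd.DataFrame, ref: ReferenceSet) -> pd.DataFrame:
    """Refine transposon/intergenic assignments.

    Transposon-assigned inserts gain an exact-match repeat-family label (or
    none); transposon- and intergenic-assigned inserts gain a piRNA-cluster
    membership flag with cluster id and strand of their first placement.
    """
    out = assignments.copy()
    out["family"] = ""
    out["in_cluster"] = False
    out["cluster"] = ""
    out["cluster_strand"] = ""

    transposon = out.index[out["category"] == "transposon"]
    for seq in transposon:
        for name, fam_seq in ref.repeat_families.items():
            if seq in fam_seq or revcomp(seq) in fam_seq:
                out.loc[seq, "family"] = name
                break

    candidates = out.index[out["category"].isin(["transposon", "intergenic"])]
    hits = locate_in_clusters(list(candidates), ref)
    first = hits.drop_duplicates("sequence").set_index("sequence")
    out.loc[first.index, "in_cluster"] = True
    out.loc[first.index, "cluster"] = first["cluster"]
    out.loc[first.index, "cluster_strand"] = first["strand"]
    return out


def composition(assignments: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Read-weighted category percentages per sample (columns sum to 100).

    Rows are the ten categories in hierarchy order plus ``unassigned``;
    columns are samples.
    """
    cats = list(CATEGORY_ORDER) + ["unassigned"]
    table = pd.DataFrame(0.0, index=cats, columns=records.columns)
    grouped = records.groupby(assignments["category"]).sum()
    for cat in grouped.index:
        table.loc[cat] = grouped.loc[cat].astype(float)
    totals = table.sum(axis=0)
    totals = totals.replace(0, np.nan)
    table = table.div(totals, axis=1) * 100.0
    table.index.name = "category"
    return table
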