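"""Transposon-derived siRNA/piRNA signature analysis.

Transposon-derived reads are partitioned by length: 21 nt reads are
endo-siRNAs, 23-29 nt reads are piRNAs, everything else (15-20 and 22 nt)
is "other" and excluded from piRNA statistics.  The ping-pong amplification
signature is measured as the 5'-to-5' offset spectrum between plus- and
minus-strand reads on a common reference: for a plus read with 5' end at p
and a minus read with 5' genomic coordinate q, the offset is
d = q - p + 1, so an exact 10-nt 5' overlap scores d = 10.  The second
piRNA signature is positional base bias: U at read position 1 (initiators)
and A at position 10 (responders).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SIRNA_LENGTH = 21
PIRNA_RANGE = (23, 29)
BASES = ("A", "C", "G", "U")
BIAS_POSITIONS = 20
SPECTRUM_HALF_WIDTH = 30


def partition_by_size(lengths: pd.Series) -> pd.Series:
    """Classify read lengths: 21 -> siRNA, 23-29 -> piRNA, else other."""
    lo, hi = PIRNA_RANGE

    def one(n: int) -> str:
        if n == SIRNA_LENGTH:
            return "siRNA"
        if lo <= n <= hi:
            return "piRNA"
        return "other"

    out = lengths.map(one)
    out.name = "size_class"
    return out


def pingpong_spectrum(
    reads: pd.DataFrame,
    L: int = SPECTRUM_HALF_WIDTH,
    weight_by_multiplicity: bool = False,
) -> pd.Series:
    """5'-to-5' offset spectrum between opposite-strand reads.

    ``reads`` needs columns ``contig`` (or ``reference``), ``five_prime``
    (genomic coordinate of the 5' end), ``strand`` (+/-) and, for the
    multiplicity-normalised variant, ``multiplicity``.  All plus/minus pairs
    within a reference contribute; offsets outside [-L, L] are dropped.
    Returns a Series indexed by offset d (d = 10 means a 10-nt 5' overlap).
    """
    ref_col = "contig" if "contig" in reads.columns else "reference"
    required = {ref_col, "five_prime", "strand"}
    if not required.issubset(reads.columns):
        raise ValueError(f"reads need columns {sorted(required)}")
    if reads["strand"].isna().any() or reads["five_prime"].isna().any():
        raise ValueError("reads without strand or position")

    offsets = np.arange(-L, L + 1)
    spectrum = pd.Series(0.0, index=pd.Index(offsets, name="offset"))
    for _, grp in reads.groupby(ref_col):
        plus = grp[grp["strand"] == "+"]
        minus = grp[grp["strand"] == "-"]
        if plus.empty or minus.empty:
            continue
        p = plus["five_prime"].to_numpy(dtype=np.int64)
        q = minus["five_prime"].to_numpy(dtype=np.int64)
        if weight_by_multiplicity:
            wp = 1.0 / plus["multiplicity"].to_numpy(dtype=float)
            wq = 1.0 / minus["multiplicity"].to_numpy(dtype=float)
        else:
            wp = np.ones(len(p))
            wq = np.ones(len(q))
        d = (q[None, :] - p[:, None] + 1).ravel()
        w = (wp[:, None] * wq[None, :]).ravel()
        keep = (d >= -L) & (d <= L)
        binned = np.bincount(d[keep] + L, weights=w[keep], minlength=2 * L + 1)
        spectrum += binned
    if not weight_by_multiplicity:
        spectrum = spectrum.astype(int)
    return spectrum


def pair_participants(reads: pd.DataFrame, overlap_nt: int = 10) -> pd.DataFrame:
    """Reads participating in at least one exact ``overlap_nt`` 5' overlap pair."""
    ref_col = "contig" if "contig" in reads.columns else "reference"
    keep = np.zeros(len(reads), dtype=bool)
    idx = pd.Series(np.arange(len(reads)), index=reads.index)
    for _, grp in reads.groupby(ref_col):
        plus = grp[grp["strand"] == "+"]
        minus = grp[grp["strand"] == "-"]
        q_set = set(minus["five_prime"])
        p_set = set(plus["five_prime"])
        for rid, p in plus["five_prime"].items():
            if p + overlap_nt - 1 in q_set:
                keep[idx[rid]] = True
        for rid, q in minus["five_prime"].items():
            if q - overlap_nt + 1 in p_set:
                keep[idx[rid]] = True
    return reads[keep]


def base_bias(
    sequences: pd.Series | list[str], positions: int = BIAS_POSITIONS
) -> pd.DataFrame:
    """Position x base frequency matrix over the first ``positions`` positions.

    Frequencies at each 1-based position are computed over the reads that
    cover it and sum to 1.  T is reported as U (RNA display convention).
    The table is logo-ready (rows = positions, columns = A/C/G/U).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty read set")
    counts = np.zeros((positions, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for seq in seqs:
        for i, ch in enumerate(seq[:positions]):
            j = base_idx.get(ch)
            if j is not None:
                counts[i, j] += 1
    cover = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = counts / cover
    out = pd.DataFrame(
        freq,
        index=pd.RangeIndex(1, positions + 1, name="position"),
        columns=["A", "C", "G", "U"],
    )
    return out


def strand_profile(
    reads: pd.DataFrame, clusters: pd.DataFrame, bins: int = 50
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Binned plus/minus 5'-end counts along each piRNA cluster.

    Returns ``(profile, bias, n_outside)``: ``profile`` has one row per
    (cluster, bin) with plus/minus counts, ``bias`` is the per-cluster
    plus/(plus+minus) statistic (NaN for clusters without reads) and
    ``n_outside`` tallies reads falling in no cluster.
    """
    rows = []
    bias = {}
    outside = np.ones(len(reads), dtype=bool)
    pos = reads["five_prime"].to_numpy()
    contig = reads["contig"].to_numpy()
    strand = reads["strand"].to_numpy()
    for _, cl in clusters.iterrows():
        name, start, end = cl["name"], cl["start"], cl["end"]
        inside = (contig == cl["contig"]) & (pos >= start) & (pos < end)
        outside &= ~inside
        edges = np.linspace(start, end, bins + 1)
        which = np.clip(np.searchsorted(edges, pos[inside], side="right") - 1, 0, bins - 1)
        plus_in = strand[inside] == "+"
        for b in range(bins):
            sel = which == b
            rows.append({
                "cluster": name, "bin": b,
                "start": int(edges[b]), "end": int(edges[b + 1]),
                "plus": int((sel & plus_in).sum()),
                "minus": int((sel & ~plus_in).sum()),
            })
        n_plus, n_minus = int(plus_in.sum()), int((~plus_in).sum())
        total = n_plus + n_minus
        bias[name] = n_plus / total if total else float("nan")
    profile = pd.DataFrame(rows, columns=["cluster", "bin", "start", "end", "plus", "minus"])
    return profile, pd.Series(bias, name="plus_bias"), int(outside.sum())


def stage_composition(
    libraries: dict[str, tuple[pd.DataFrame, pd.Series]]
) -> pd.DataFrame:
    """Per-library transposon share and its 21-nt vs 23-29-nt split.

    ``libraries`` maps library name to ``(records, categories)`` where
    ``records`` is a collapsed insert table with a single count column (or a
    ``count`` column) and ``categories`` assigns each insert its annotation
    category.  Returns percentages of all reads: transposon total, the
    siRNA (21 nt) and piRNA (23-29 nt) shares within it, and the remainder.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries to compare")
    rows = []
    for name, (records, categories) in libraries.items():
        counts = records["count"] if "count" in records.columns else records.sum(axis=1)
        total = counts.sum()
        is_tn = categories.reindex(counts.index) == "transposon"
        tn_counts = counts[is_tn]
        sizes = partition_by_size(pd.Series([len(s) for s in tn_counts.index],
                                            index=tn_counts.index))
        tn = tn_counts.sum()
        si = tn_counts[sizes == "siRNA"].sum()
        pi = tn_counts[sizes == "piRNA"].sum()
        pct = lambda x: 100.0 * x / total if total else float("nan")
        rows.append({
            "library": name,
            "transposon_pct": pct(tn),
            "sirna_21nt_pct": pct(si),
            "pirna_23_29nt_pct": pct(pi),
            "transposon_other_pct": pct(tn - si - pi),
        })
    return pd.DataFrame(rows).set_index("library")
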