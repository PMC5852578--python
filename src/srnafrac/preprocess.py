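"""Demultiplexing, 3'-adapter trimming cascade and insert collapsing.

The trimming cascade works on the read remainder left after barcode removal
(32 nt with the default 36-nt reads and 4-nt barcodes) and proceeds in four
steps:

1. leftmost exact occurrence of the full 25-nt adapter; the prefix before it
   is the insert (accepted from 7 nt up, shorter prefixes are rejected);
2. otherwise the adapter is shortened from its 3' end one base at a time
   down to 4 nt and matched against the remainder's 3' terminus, which
   identifies inserts of 8-28 nt;
3. otherwise steps 1-2 are repeated allowing up to two substitutions over an
   adapter match of at least 10 nt (fewest mismatches, then longest match,
   then leftmost position wins);
4. any trimmed insert is screened: poly(A) inserts and inserts with more
   than one N are rejected.

Inserts of 15-29 nt are then collapsed to unique sequences with per-sample
counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

MIN_FULL_INSERT = 7        # minimum insert under a full-adapter hit
MIN_STEPWISE_ADAPTER = 4   # smallest adapter prefix matched at the 3' terminus
MIN_MISMATCH_ADAPTER = 10  # smallest adapter match allowed with mismatches
MAX_MISMATCHES = 2
COLLAPSE_RANGE = (15, 29)  # insert length window retained for analysis
POLYA_FRACTION = 0.9


class TrimOutcome(str, Enum):
    TRIMMED_FULL = "trimmed_full"
    TRIMMED_STEPWISE = "trimmed_stepwise"
    TRIMMED_MISMATCH = "trimmed_mismatch"
    REJECTED_SHORT = "rejected_short"
    REJECTED_POLYA = "rejected_polyA"
    REJECTED_N = "rejected_N"
    UNTRIMMED = "untrimmed"

    @property
    def trimmed(self) -> bool:
        return self.value.startswith("trimmed")


@dataclass(frozen=True)
class TrimResult:
    outcome: TrimOutcome
    insert: str = ""


def demultiplex(
    reads: pd.DataFrame, barcode_map: dict[str, str]
) -> tuple[dict[str, pd.DataFrame], int]:
    """Split reads by exact barcode prefix, stripping the barcode.

    A read is assigned iff its prefix equals exactly one barcode; reads with
    any ambiguity (no match, or an N anywhere in the barcode region) are
    discarded.  Returns ``(sample -> reads, n_discarded)``.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode_map")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    bc_len = lengths.pop()
    lookup = {bc: sid for sid, bc in barcode_map.items()}

    buckets: dict[str, list[dict]] = {sid: [] for sid in barcode_map}
    discarded = 0
    for row in reads.itertuples():
        prefix = row.sequence[:bc_len]
        sid = lookup.get(prefix)
        if sid is None or "N" in prefix:
            discarded += 1
            continue
        buckets[sid].append({"read_id": row.read_id, "sequence": row.sequence[bc_len:]})
    out = {
        sid: pd.DataFrame(rows, columns=["read_id", "sequence"])
        for sid, rows in buckets.items()
    }
    assert sum(len(df) for df in out.values()) + discarded == len(reads)
    return out, discarded


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _screen(insert: str, outcome: TrimOutcome) -> TrimResult:
    """Step 4: poly(A) and multiple-N screen on a trimmed insert."""
    if insert and insert.count("A") / len(insert) >= POLYA_FRACTION:
        return TrimResult(TrimOutcome.REJECTED_POLYA)
    if insert.count("N") > 1:
        return TrimResult(TrimOutcome.REJECTED_N)
    return TrimResult(outcome, insert)


def trim_adapter(remainder: str, adapter: str) -> TrimResult:
    """Run the 4-step trimming cascade on a barcode-stripped read."""
    alen = len(adapter)
    # step 1: leftmost exact full adapter
    pos = remainder.find(adapter)
    if pos >= 0:
        if pos < MIN_FULL_INSERT:
            return TrimResult(TrimOutcome.REJECTED_SHORT)
        return _screen(remainder[:pos], TrimOutcome.TRIMMED_FULL)
    # step 2: exact adapter prefix at the 3' terminus, longest first
    for k in range(alen - 1, MIN_STEPWISE_ADAPTER - 1, -1):
        if len(remainder) >= k and remainder.endswith(adapter[:k]):
            return _screen(remainder[:len(remainder) - k], TrimOutcome.TRIMMED_STEPWISE)
    # step 3: the same two searches allowing mismatches; candidates ranked by
    # fewest mismatches, then longest adapter match, then leftmost position
    best: tuple[int, int, int] | None = None   # (mismatches, -match_len, cut)
    for cut in range(0, len(remainder) - alen + 1):
        mm = _hamming(remainder[cut:cut + alen], adapter)
        if mm <= MAX_MISMATCHES:
            cand = (mm, -alen, cut)
            if best is None or cand < best:
                best = cand
    for k in range(alen - 1, MIN_MISMATCH_ADAPTER - 1, -1):
        if len(remainder) < k:
            continue
        cut = len(remainder) - k
        mm = _hamming(remainder[cut:], adapter[:k])
        if mm <= MAX_MISMATCHES:
            cand = (mm, -k, cut)
            if best is None or cand < best:
                best = cand
    if best is not None:
        cut = best[2]
        if cut < MIN_FULL_INSERT:
            return TrimResult(TrimOutcome.REJECTED_SHORT)
        return _screen(remainder[:cut], TrimOutcome.TRIMMED_MISMATCH)
    return TrimResult(TrimOutcome.UNTRIMMED)


def trim_sample(
    reads: pd.DataFrame, adapter: str
) -> tuple[list[str], Counter]:
    """Trim every read of one sample; returns retained inserts and outcome tallies."""
    inserts: list[str] = []
    tally: Counter = Counter()
    for seq in reads["sequence"]:
        res = trim_adapter(seq, adapter)
        tally[res.outcome.value] += 1
        if res.outcome.trimmed:
            inserts.append(res.insert)
    assert sum(tally.values()) == len(reads)
    return inserts, tally


def collapse(
    inserts_per_sample: dict[str, list[str]],
    length_range: tuple[int, int] = COLLAPSE_RANGE,
) -> pd.DataFrame:
    """Collapse trimmed inserts to unique sequences with per-sample counts.

    Only inserts within ``length_range`` (inclusive) are retained.  Returns a
    DataFrame indexed by insert sequence with one count column per sample.
    """
    lo, hi = length_range
    counters = {
        sid: Counter(s for s in inserts if lo <= len(s) <= hi)
        for sid, inserts in inserts_per_sample.items()
    }
    table = pd.DataFrame(counters).fillna(0).astype(int)
    table.index.name = "sequence"
    for sid in inserts_per_sample:
        if sid not in table.columns:
            table[sid] = 0
    if len(table):
        table = table[list(inserts_per_sample)]
        table = table.sort_index()
    return table


def run_preprocess(
    reads: pd.DataFrame,
    barcode_map: dict[str, str],
    adapter: str,
    length_range: tuple[int, int] = COLLAPSE_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demultiplex, trim and collapse a raw multiplexed read set.

    Returns ``(records, summary)`` where ``records`` is the collapsed
    insert x sample count table and ``summary`` tallies per-sample trimming
    outcomes (plus the pool of barcode-ambiguous reads under ``discarded``).
    """
    by_sample, discarded = demultiplex(reads, barcode_map)
    inserts: dict[str, list[str]] = {}
    tallies: dict[str, Counter] = {}
    for sid, df in by_sample.items():
        inserts[sid], tallies[sid] = trim_sample(df, adapter)
    summary = pd.DataFrame(tallies).fillna(0).astype(int).T
    summary.index.name = "sample"
    summary["input_reads"] = [len(by_sample[sid]) for sid in summary.index]
    summary.attrs["discarded_barcode"] = discarded
    records = collapse(inserts, length_range)
    return records, summary
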