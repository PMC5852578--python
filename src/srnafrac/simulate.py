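"""Synthetic reference collections and multiplexed small-RNA libraries.

Every read carries full ground-truth provenance (sample, source category,
source sequence, strand, intended insert, size class, ping-pong partner), so
each downstream stage of the pipeline can be validated without any external
download.  Reads are 36-nt cDNA-style sequences: 4-nt barcode + insert + as
much of the 25-nt 3' adapter as fits.

piRNA-sized reads are produced by an explicit ping-pong construction on a
miniature two-contig genome: an initiator (plus strand, 5' end at p) and its
responder (minus strand) whose 5' ends overlap by exactly ``overlap_nt``
(default 10).  Because the initiator's position 1 and the responder's
position 10 are complementary views of the same genomic base, the 1U/10A
biases are realised by biased selection of the pair's anchor site among
genomic T positions, which keeps every read an exact substring (or reverse
complement) of its source — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    SIM_CATEGORY_TO_ANNOT,
    SimulationConfig,
    sample_id,
)

#: Hierarchical annotation order (highest priority first).
CATEGORY_ORDER = (
    "rRNA", "miRNA", "tRNA", "miscRNA", "ncRNA",
    "transposon", "transcript", "intron", "pseudogene", "intergenic",
)

MIN_INSERT, MAX_INSERT = 15, 29

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Reference sequence lengths per category (nt); all must be >= MAX_INSERT.
DEFAULT_CATEGORY_LENGTHS = {
    "rRNA": 300, "miRNA": 90, "tRNA": 72, "miscRNA": 150, "ncRNA": 200,
    "transposon": 400, "transcript": 300, "intron": 250, "pseudogene": 250,
    "intergenic": 300,
}

MATURE_OFFSET = 15   # mature miRNA 5' offset within its hairpin
MATURE_LENGTH = 22


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_ALPHABET, size=n).tobytes().decode()


@dataclass(frozen=True)
class ClusterCopy:
    """One source segment embedded inside a piRNA cluster interval."""

    contig: str
    start: int       # 0-based half-open genomic coordinates
    end: int
    source: str      # repeat family (or intergenic sequence) name
    strand: str      # orientation of the embedded copy
    cluster: str


@dataclass
class ReferenceSet:
    """Ordered, category-labelled reference sequences plus genomic annotation.

    ``categories`` maps each annotation category (in hierarchy order) to
    ``{name: sequence}``.  ``mature_mirnas`` gives each mature miRNA's
    0-based half-open coordinates within its hairpin and its genomic cluster
    id.  ``pirna_clusters`` holds 0-based half-open intervals on the
    miniature genome; ``cluster_copies`` records the strand-resolvable
    origin of every segment inside them.
    """

    categories: dict[str, dict[str, str]]
    mature_mirnas: pd.DataFrame
    pirna_clusters: pd.DataFrame
    genome: dict[str, str]
    repeat_families: dict[str, str]
    trnas_cca: dict[str, str]
    cluster_copies: list[ClusterCopy] = field(default_factory=list)

    def validate(self) -> None:
        for cat in CATEGORY_ORDER:
            if cat not in self.categories:
                raise ValueError(f"missing category {cat!r}")
        for _, row in self.mature_mirnas.iterrows():
            hp = self.categories["miRNA"][row["hairpin"]]
            if hp[row["start"]:row["end"]] != row["sequence"]:
                raise ValueError(
                    f"mature miRNA {row['name']} is not a substring of its hairpin"
                )
        bad = self.pirna_clusters.query("start >= end")
        if len(bad):
            raise ValueError("piRNA cluster intervals must have start < end")


def build_reference(config: SimulationConfig) -> ReferenceSet:
    """Generate a deterministic :class:`ReferenceSet` from ``config.seed``.

    Categories are mutually non-identical and, being independent random
    sequences, share no 15-29-mers in practice, which is what makes exact
    tier-0 category recovery a meaningful test downstream.
    """
    lengths = dict(DEFAULT_CATEGORY_LENGTHS)
    short = {c: n for c, n in lengths.items() if n < MAX_INSERT}
    if short:
        raise ValueError(
            f"category sequence lengths must be >= {MAX_INSERT} nt: {short}"
        )
    rng = np.random.default_rng(config.seed)
    counts = {
        "rRNA": config.n_rrnas, "miRNA": config.n_hairpins,
        "tRNA": config.n_trnas, "miscRNA": config.n_miscrna,
        "ncRNA": config.n_ncrna, "transposon": config.n_transposons,
        "transcript": config.n_transcripts, "intron": config.n_introns,
        "pseudogene": config.n_pseudogenes, "intergenic": config.n_intergenic,
    }
    categories: dict[str, dict[str, str]] = {}
    for cat in CATEGORY_ORDER:
        if counts[cat] < 1:
            raise ValueError(f"at least one sequence required for category {cat}")
        categories[cat] = {
            f"{cat}-{i + 1}": _random_seq(rng, lengths[cat])
            for i in range(counts[cat])
        }

    # tRNAs are reported CCA-appended (the mature, chargeable form)
    trnas_cca = {n: s + "CCA" for n, s in categories["tRNA"].items()}
    categories["tRNA"] = trnas_cca

    # mature miRNAs: one per hairpin, grouped into genomic clusters of <= 3
    rows = []
    cluster_idx, in_cluster = 0, 0
    sizes = rng.integers(1, 4, size=counts["miRNA"])
    cluster_of = []
    for sz in sizes:
        cluster_idx += 1
        cluster_of.extend([f"mir-cluster-{cluster_idx}"] * int(sz))
    for i, (hp_name, hp_seq) in enumerate(categories["miRNA"].items()):
        start, end = MATURE_OFFSET, MATURE_OFFSET + MATURE_LENGTH
        rows.append({
            "name": f"mir-{i + 1}",
            "hairpin": hp_name,
            "start": start,
            "end": end,
            "sequence": hp_seq[start:end],
            "cluster": cluster_of[i],
        })
    mature = pd.DataFrame(rows)

    repeat_families = {
        f"repfam-{i + 1}": seq
        for i, seq in enumerate(categories["transposon"].values())
    }

    # miniature genome: chr1 carries one copy of every reference sequence,
    # chr2 carries two piRNA clusters built from transposon copies (both
    # orientations, emulating a dual-strand cluster) plus one intergenic
    # stretch inside the first cluster.
    spacer = lambda n: _random_seq(rng, n)
    chr1_parts, pos = [], 0
    for cat in CATEGORY_ORDER:
        for seq in categories[cat].values():
            chr1_parts.append(spacer(40))
            chr1_parts.append(seq)
    chr1_parts.append(spacer(40))
    chr1 = "".join(chr1_parts)

    fam_names = list(repeat_families)
    fam = lambda i: fam_names[i % len(fam_names)]
    plans = [
        # (cluster name, [(source name, strand)])
        ("cluster-1", [(fam(0), "+"), (fam(1), "-"),
                       ("intergenic-1", "+"),
                       (fam(2), "+"), (fam(3), "-")]),
        ("cluster-2", [(fam(4), "+"), (fam(0), "-"),
                       (fam(2), "-"), (fam(1), "+")]),
    ]
    chr2_parts, copies, intervals = [], [], []
    pos = 0

    def _append(seq: str) -> tuple[int, int]:
        nonlocal pos
        chr2_parts.append(seq)
        start = pos
        pos += len(seq)
        return start, pos

    _append(spacer(60))
    for cname, layout in plans:
        cstart = pos
        for source, strand in layout:
            seq = repeat_families.get(source, categories["intergenic"].get(source))
            if strand == "-":
                seq = revcomp(seq)
            s, e = _append(seq)
            copies.append(ClusterCopy("chr2", s, e, source, strand, cname))
        intervals.append({"contig": "chr2", "start": cstart, "end": pos, "name": cname})
        _append(spacer(60))
    chr2 = "".join(chr2_parts)

    ref = ReferenceSet(
        categories=categories,
        mature_mirnas=mature,
        pirna_clusters=pd.DataFrame(intervals),
        genome={"chr1": chr1, "chr2": chr2},
        repeat_families=repeat_families,
        trnas_cca=trnas_cca,
        cluster_copies=copies,
    )
    ref.validate()
    _check_disjoint(categories)
    return ref


def _check_disjoint(categories: dict[str, dict[str, str]]) -> None:
    seen: dict[str, str] = {}
    for cat, seqs in categories.items():
        for name, seq in seqs.items():
            if seq in seen:
                raise ValueError(
                    f"sequence shared verbatim across categories: {seen[seq]} / {cat}:{name}"
                )
            seen[seq] = f"{cat}:{name}"


# ---------------------------------------------------------------------------
# ping-pong simulation
# ---------------------------------------------------------------------------

_PP_COLUMNS = [
    "read_id", "contig", "five_prime", "start", "end", "strand",
    "length", "sequence", "role", "partner", "cluster", "source",
]


def simulate_pingpong(
    ref: ReferenceSet,
    config: SimulationConfig,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "pp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate positioned piRNA-sized reads from the cluster regions.

    A fraction ``pair_fraction`` of reads come in initiator/responder pairs
    whose 5' ends overlap by exactly ``overlap_nt``; the remainder are placed
    uniformly.  Returns ``(reads, ground_truth)`` where ``reads`` has one row
    per read with genomic position, strand and sequence.
    """
    pp = config.pingpong
    lo, hi = config.pirna_length_range
    if pp.overlap_nt >= lo:
        raise ValueError("overlap_nt must be smaller than the minimum piRNA length")
    n = config.reads_per_sample if n_reads is None else n_reads
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_pairs = min(n // 2, int(round(n * pp.pair_fraction / 2)))
    n_background = n - 2 * n_pairs

    copies = [c for c in ref.cluster_copies if c.source in ref.repeat_families]
    genome = ref.genome
    # valid anchor sites p for a pair: initiator [p, p+len-1] and responder
    # [p+overlap-len, p+overlap-1] must both fit inside the copy
    margin = hi - pp.overlap_nt
    site_pool: list[tuple[ClusterCopy, np.ndarray, np.ndarray]] = []
    for c in copies:
        p_lo, p_hi = c.start + margin, c.end - hi  # inclusive bounds
        if p_hi < p_lo:
            continue
        window = np.arange(p_lo, p_hi + 1)
        bases = np.frombuffer(
            genome[c.contig].encode()[p_lo:p_hi + 1], dtype="S1"
        )
        site_pool.append((c, window[bases == b"T"], window[bases != b"T"]))
    if not site_pool:
        raise ValueError("no cluster copy is long enough for ping-pong sampling")

    # with an exact overlap the 1U (initiator) and 10A (responder) biases
    # constrain the same genomic base; pairs anchor on a T with the mean of
    # the two probabilities
    t_prob = (pp.u1_bias + pp.a10_bias) / 2.0

    rows: list[dict] = []
    counter = 0

    def _read(contig, five_prime, strand, length, role, partner, cluster, source):
        nonlocal counter
        if strand == "+":
            s, e = five_prime, five_prime + length
            seq = genome[contig][s:e]
        else:
            s, e = five_prime - length + 1, five_prime + 1
            seq = revcomp(genome[contig][s:e])
        rid = f"{id_prefix}_{counter:06d}"
        counter += 1
        rows.append({
            "read_id": rid, "contig": contig, "five_prime": five_prime,
            "start": s, "end": e, "strand": strand, "length": length,
            "sequence": seq, "role": role, "partner": partner,
            "cluster": cluster, "source": source,
        })
        return rid

    for _ in range(n_pairs):
        copy, t_sites, other_sites = site_pool[rng.integers(len(site_pool))]
        want_t = rng.random() < t_prob
        sites = t_sites if (want_t and len(t_sites)) else other_sites
        if not len(sites):
            sites = np.concatenate([t_sites, other_sites])
        p = int(sites[rng.integers(len(sites))])
        li = int(rng.integers(lo, hi + 1))
        lr = int(rng.integers(lo, hi + 1))
        q = p + pp.overlap_nt - 1
        init_id = f"{id_prefix}_{counter:06d}"
        resp_id = f"{id_prefix}_{counter + 1:06d}"
        _read(copy.contig, p, "+", li, "initiator", resp_id, copy.cluster, copy.source)
        _read(copy.contig, q, "-", lr, "responder", init_id, copy.cluster, copy.source)

    for _ in range(n_background):
        copy = copies[rng.integers(len(copies))]
        length = int(rng.integers(lo, hi + 1))
        if copy.end - copy.start < length:
            continue
        start = int(rng.integers(copy.start, copy.end - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        five = start if strand == "+" else start + length - 1
        _read(copy.contig, five, strand, length, "background", "", copy.cluster, copy.source)

    reads = pd.DataFrame(rows, columns=_PP_COLUMNS)
    gt = reads.rename(columns={"source": "source_name"})[
        ["read_id", "source_name", "strand", "sequence", "role", "partner", "cluster"]
    ].copy()
    gt.insert(1, "category", "transposon")
    gt["size_class"] = "piRNA"
    return reads, gt


# ---------------------------------------------------------------------------
# full multiplexed library
# ---------------------------------------------------------------------------

GT_COLUMNS = [
    "read_id", "sample", "sim_category", "category", "source_name", "strand",
    "insert", "insert_length", "size_class", "partner", "contig", "five_prime",
]

_ISOMIR_SHIFTS = np.array([-3, -2, -1, 0, 1, 2, 3])
_ISOMIR_PROBS = np.array([0.01, 0.04, 0.10, 0.70, 0.10, 0.04, 0.01])


def simulate_library(
    ref: ReferenceSet, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full multiplexed raw-read set for every configured sample.

    Returns ``(reads, ground_truth)``: ``reads`` has columns ``read_id`` and
    ``sequence`` (fixed ``read_length``); ``ground_truth`` has one row per
    emitted read.  Each read is ``barcode + insert + adapter`` truncated (or
    A-padded) to ``read_length``.
    """
    rng = np.random.default_rng(config.seed)
    bc_len = len(next(iter(config.barcode_map.values())))
    max_insert = config.read_length - bc_len
    if config.pirna_length_range[1] > max_insert or config.insert_length_range[1] > max_insert:
        raise ValueError(
            f"insert longer than read_length - barcode length ({max_insert} nt) requested"
        )

    read_rows: list[dict] = []
    gt_rows: list[dict] = []

    matures = ref.mature_mirnas
    trna_names = list(ref.trnas_cca)
    tn_names = list(ref.categories["transposon"])

    for stage, fraction in config.samples:
        sid = sample_id(stage, fraction)
        barcode = config.barcode_map[sid]
        comp = config.composition[(stage, fraction)]
        cats = list(comp)
        draws = rng.choice(len(cats), size=config.reads_per_sample, p=[comp[c] for c in cats])
        n_pirna = int(np.sum(draws == cats.index("pirna"))) if "pirna" in cats else 0
        pp_reads, _ = simulate_pingpong(
            ref, config, n_reads=n_pirna, rng=rng, id_prefix=f"{sid}_pp"
        ) if n_pirna else (pd.DataFrame(columns=_PP_COLUMNS), None)
        pp_iter = pp_reads.itertuples()
        pp_to_lib: dict[str, str] = {}    # internal ping-pong id -> library read id

        for i, ci in enumerate(draws):
            cat = cats[ci]
            rid = f"{sid}_r{i:06d}"
            strand, source, partner, contig, five = "+", "", "", "", -1
            if cat == "mirna":
                m = matures.iloc[int(rng.integers(len(matures)))]
                hp = ref.categories["miRNA"][m["hairpin"]]
                shift = int(rng.choice(_ISOMIR_SHIFTS, p=_ISOMIR_PROBS))
                start = min(max(m["start"] + shift, 0), len(hp) - MATURE_LENGTH)
                insert = hp[start:start + MATURE_LENGTH]
                source = m["name"]
                insert = _apply_variants(
                    insert, start, m, config.planted_variants, rng
                )
            elif cat == "trf":
                name = trna_names[int(rng.integers(len(trna_names)))]
                seq = ref.trnas_cca[name]
                length = int(rng.integers(*_clip_range(config.insert_length_range, len(seq))))
                insert = seq[-length:] if rng.random() < 0.5 else seq[:length]
                source = name
            elif cat == "sirna":
                name = tn_names[int(rng.integers(len(tn_names)))]
                seq = ref.categories["transposon"][name]
                length = config.sirna_length
                start = int(rng.integers(0, len(seq) - length + 1))
                insert = seq[start:start + length]
                if rng.random() < 0.5:
                    insert, strand = revcomp(insert), "-"
                source = name
            elif cat == "pirna":
                row = next(pp_iter)
                insert = row.sequence
                strand, source, partner = row.strand, row.source, row.partner
                contig, five = row.contig, row.five_prime
                pp_to_lib[row.read_id] = rid
            else:
                annot = SIM_CATEGORY_TO_ANNOT[cat]
                names = list(ref.categories[annot])
                name = names[int(rng.integers(len(names)))]
                seq = ref.categories[annot][name]
                length = int(rng.integers(*_clip_range(config.insert_length_range, len(seq))))
                start = int(rng.integers(0, len(seq) - length + 1))
                insert = seq[start:start + length]
                source = name
            read = (barcode + insert + config.adapter)
            if len(read) < config.read_length:
                read = read + "A" * (config.read_length - len(read))
            read = read[:config.read_length]
            read_rows.append({"read_id": rid, "sequence": read})
            gt_rows.append({
                "read_id": rid, "sample": sid, "sim_category": cat,
                "category": SIM_CATEGORY_TO_ANNOT[cat], "source_name": source,
                "strand": strand, "insert": insert,
                "insert_length": len(insert),
                "size_class": _size_class_of(cat),
                "partner": partner, "contig": contig, "five_prime": five,
            })

        if pp_to_lib:
            for row in gt_rows:
                if row["sample"] == sid and row["partner"]:
                    row["partner"] = pp_to_lib.get(row["partner"], "")

    reads = pd.DataFrame(read_rows, columns=["read_id", "sequence"])
    gt = pd.DataFrame(gt_rows, columns=GT_COLUMNS)
    return reads, gt


def _size_class_of(cat: str) -> str:
    return {"sirna": "siRNA", "pirna": "piRNA"}.get(cat, "other")


def _clip_range(rng_pair: tuple[int, int], seq_len: int) -> tuple[int, int]:
    lo, hi = rng_pair
    hi = min(hi, seq_len)
    return lo, hi + 1


def _apply_variants(insert, start, mature, variants, rng):
    for name, pos, ref_base, alt, fraction in variants:
        if name != mature["name"]:
            continue
        site = mature["start"] + pos - 1      # hairpin coordinate of the variant
        idx = site - start
        if 0 <= idx < len(insert) and rng.random() < fraction:
            if insert[idx] == ref_base:
                insert = insert[:idx] + alt + insert[idx + 1:]
    return insert
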