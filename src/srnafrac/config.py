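"""Simulation configuration for synthetic polysome-fractionated small-RNA libraries.

The defaults emulate the layout of the study design this package analyses:
two developmental stages (0-1 h and 7-8 h embryos), each sequenced
unfractionated (UF) and in four sucrose-gradient fractions (mRNP, 60S,
80S/monosome, polysome), multiplexed with 4-nt barcodes into 36-nt reads
carrying a 25-nt 3' adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

#: 3' sequencing adapter ligated to every insert (25 nt).
DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTGT"

STAGES = ("0-1h", "7-8h")
FRACTIONS = ("UF", "mRNP", "60S", "80S", "Poly")

#: Simulation source categories and the annotation category each maps to.
SIM_CATEGORY_TO_ANNOT = {
    "mirna": "miRNA",
    "trf": "tRNA",
    "rrna": "rRNA",
    "sirna": "transposon",
    "pirna": "transposon",
    "transcript": "transcript",
    "miscrna": "miscRNA",
    "ncrna": "ncRNA",
    "intron": "intron",
    "pseudogene": "pseudogene",
    "intergenic": "intergenic",
}

#: Fixed, pairwise-distinct 4-nt sample barcodes (one per stage x fraction).
DEFAULT_BARCODES = (
    "AACT", "AAGG", "ACAC", "AGTA", "CATG",
    "CCAA", "CTTC", "GAGT", "GTCA", "TGAT",
)

# Per-sample source composition. Stage/fraction trends mirror the biology the
# simulator emulates: transposon-derived piRNAs dominate early embryos and
# co-sediment with polysomes, 21-nt siRNAs rise post-MZT and sit in the mRNP
# fraction, tRFs are mRNP-enriched, rRNA fragments follow ribosome content,
# and miRNAs rise in the later stage.
DEFAULT_COMPOSITION = {
    ("0-1h", "UF"):   {"rrna": 0.15, "mirna": 0.20, "trf": 0.15, "sirna": 0.05, "pirna": 0.25, "transcript": 0.20},
    ("0-1h", "mRNP"): {"rrna": 0.10, "mirna": 0.20, "trf": 0.30, "sirna": 0.10, "pirna": 0.15, "transcript": 0.15},
    ("0-1h", "60S"):  {"rrna": 0.20, "mirna": 0.25, "trf": 0.15, "sirna": 0.05, "pirna": 0.20, "transcript": 0.15},
    ("0-1h", "80S"):  {"rrna": 0.25, "mirna": 0.20, "trf": 0.10, "sirna": 0.05, "pirna": 0.25, "transcript": 0.15},
    ("0-1h", "Poly"): {"rrna": 0.30, "mirna": 0.15, "trf": 0.05, "sirna": 0.03, "pirna": 0.32, "transcript": 0.15},
    ("7-8h", "UF"):   {"rrna": 0.30, "mirna": 0.30, "trf": 0.15, "sirna": 0.10, "pirna": 0.08, "transcript": 0.07},
    ("7-8h", "mRNP"): {"rrna": 0.10, "mirna": 0.25, "trf": 0.35, "sirna": 0.15, "pirna": 0.08, "transcript": 0.07},
    ("7-8h", "60S"):  {"rrna": 0.20, "mirna": 0.30, "trf": 0.20, "sirna": 0.10, "pirna": 0.10, "transcript": 0.10},
    ("7-8h", "80S"):  {"rrna": 0.25, "mirna": 0.30, "trf": 0.15, "sirna": 0.08, "pirna": 0.12, "transcript": 0.10},
    ("7-8h", "Poly"): {"rrna": 0.35, "mirna": 0.25, "trf": 0.05, "sirna": 0.05, "pirna": 0.20, "transcript": 0.10},
}


@dataclass(frozen=True)
class PingPongConfig:
    """Geometry and base biases of the piRNA amplification (ping-pong) cycle.

    pair_fraction
        Fraction of piRNA-sized reads generated as initiator/responder pairs
        whose 5' ends overlap by exactly ``overlap_nt``; the rest are placed
        uniformly on the cluster.
    u1_bias / a10_bias
        Probability that an initiator carries U(T) at read position 1 and a
        responder carries A at read position 10.  With an exact 10-nt 5'
        overlap these two constraints concern the same (complementary)
        genomic base, so for paired reads they are realised jointly through
        the pair's anchor site (see :mod:`srnafrac.simulate`).
    """

    pair_fraction: float = 0.9
    overlap_nt: int = 10
    u1_bias: float = 0.9
    a10_bias: float = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    barcode_map: dict[str, str] = field(default_factory=dict)
    samples: tuple[tuple[str, str], ...] = tuple(
        (s, f) for s in STAGES for f in FRACTIONS
    )
    reads_per_sample: int = 2000
    composition: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPOSITION.items()}
    )
    pingpong: PingPongConfig = field(default_factory=PingPongConfig)
    sirna_length: int = 21
    pirna_length_range: tuple[int, int] = (23, 29)
    insert_length_range: tuple[int, int] = (15, 28)
    #: (miRNA name, 1-based position, ref base, alt base, fraction of reads)
    planted_variants: tuple[tuple[str, int, str, str, float], ...] = ()
    # reference sizes (number of sequences per category)
    n_hairpins: int = 20
    n_trnas: int = 8
    n_rrnas: int = 3
    n_transposons: int = 5
    n_transcripts: int = 10
    n_miscrna: int = 3
    n_ncrna: int = 3
    n_introns: int = 5
    n_pseudogenes: int = 3
    n_intergenic: int = 2

    def __post_init__(self) -> None:
        if not self.barcode_map:
            bcs = dict(zip(
                (sample_id(s, f) for s, f in self.samples), DEFAULT_BARCODES
            ))
            if len(bcs) < len(self.samples):
                raise ValueError("more samples than default barcodes; supply barcode_map")
            object.__setattr__(self, "barcode_map", bcs)
        validate_config(self)

    def sample_ids(self) -> list[str]:
        return [sample_id(s, f) for s, f in self.samples]


def sample_id(stage: str, fraction: str) -> str:
    return f"{stage}_{fraction}"


def validate_config(cfg: SimulationConfig) -> None:
    lengths = {len(b) for b in cfg.barcode_map.values()}
    if len(lengths) > 1:
        raise ValueError(f"barcode lengths are not uniform: {sorted(lengths)}")
    if len(set(cfg.barcode_map.values())) != len(cfg.barcode_map):
        raise ValueError("duplicate barcodes in barcode_map")
    for key in cfg.samples:
        comp = cfg.composition.get(key)
        if comp is None:
            raise ValueError(f"no composition defined for sample {key}")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition for {key} sums to {total}, not 1")
        unknown = set(comp) - set(SIM_CATEGORY_TO_ANNOT)
        if unknown:
            raise ValueError(f"unknown composition categories {sorted(unknown)}")
    if not (0.0 <= cfg.pingpong.pair_fraction <= 1.0):
        raise ValueError("pair_fraction must lie in [0, 1]")
    if cfg.pingpong.overlap_nt >= cfg.pirna_length_range[0]:
        raise ValueError("overlap_nt must be smaller than the minimum piRNA length")
    bc_len = len(next(iter(cfg.barcode_map.values())))
    if cfg.pirna_length_range[1] > cfg.read_length - bc_len:
        raise ValueError("maximum insert length exceeds read_length - barcode length")


def with_overrides(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    """Return a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **kwargs)


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    The file may override any default; ``seed`` is mandatory.  ``samples``
    entries are ``[stage, fraction]`` pairs and composition keys are written
    ``"stage/fraction"``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("simulation config must set a seed")
    kwargs: dict = {"seed": int(raw.pop("seed"))}
    if "samples" in raw:
        kwargs["samples"] = tuple((s, f) for s, f in raw.pop("samples"))
    if "composition" in raw:
        comp = {}
        for key, table in raw.pop("composition").items():
            stage, fraction = key.split("/")
            comp[(stage, fraction)] = {c: float(p) for c, p in table.items()}
        kwargs["composition"] = comp
    if "pingpong" in raw:
        kwargs["pingpong"] = PingPongConfig(**raw.pop("pingpong"))
    for name in (
        "read_length", "adapter", "barcode_map", "reads_per_sample",
        "sirna_length", "n_hairpins", "n_trnas", "n_rrnas", "n_transposons",
        "n_transcripts",
    ):
        if name in raw:
            kwargs[name] = raw.pop(name)
    if "pirna_length_range" in raw:
        kwargs["pirna_length_range"] = tuple(raw.pop("pirna_length_range"))
    if "planted_variants" in raw:
        kwargs["planted_variants"] = tuple(
            (str(m), int(p), str(r), str(a), float(f))
            for m, p, r, a, f in raw.pop("planted_variants")
        )
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return SimulationConfig(**kwargs)
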