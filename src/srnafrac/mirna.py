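"""Mature miRNA quantification and polysome-association grouping.

Quantification counts reads that match a miRNA hairpin exactly and whose 5'
end falls within +/- 3 nt of the annotated mature 5' end (the isomiR
window).  Expression is reported in RPM (reads per million
category-assigned reads per sample).  Stage comparisons use pseudocounted
log2 fold changes, log2((RPM_7-8h + 10) / (RPM_0-1h + 10)), whose magnitude
is therefore bounded by log2((1e6 + 10) / 10).

miRNAs expressed above 50 RPM in at least one sample are classified into
four polysome-association groups from their five fold-change columns
(Tot, mRNP, 60S, 80S, Poly), with an inclusive threshold tau = 1.0 on the
log2 scale:

* G2 - |Tot| < tau (no significant change in unfractionated embryos);
* otherwise, with d the sign of Tot: G4 if no fraction column changes by
  >= tau in direction d while at least one changes by >= tau against it
  (discordant cytoplasmic behaviour); else G1 (d > 0, up in 7-8 h) or
  G3 (d < 0, down in 7-8 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .config import STAGES
from .simulate import ReferenceSet

PSEUDOCOUNT = 10.0
RPM_THRESHOLD = 50.0
TAU = 1.0
ISOMIR_WINDOW = 3
FC_COLUMNS = ("Tot", "mRNP", "60S", "80S", "Poly")
FRACTION_COLUMNS = ("mRNP", "60S", "80S", "Poly")


@dataclass
class ExpressionMatrix:
    """Mature-miRNA x sample RPM matrix with its raw-count companions."""

    rpm: pd.DataFrame
    counts: pd.DataFrame
    hairpin_counts: pd.DataFrame
    denominators: pd.Series

    def validate(self) -> None:
        if (self.rpm.values < 0).any():
            raise ValueError("negative RPM")
        # RPM conservation: sum(raw) * 1e6 / denominator == sum(RPM)
        lhs = self.counts.sum(axis=0) * 1e6 / self.denominators
        rhs = self.rpm.sum(axis=0)
        if not np.allclose(lhs.fillna(0.0), rhs.fillna(0.0)):
            raise ValueError("RPM matrix is inconsistent with raw counts")


def quantify(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    ref: ReferenceSet,
    window: int = ISOMIR_WINDOW,
    denominators: pd.Series | None = None,
) -> ExpressionMatrix:
    """Count exact hairpin-matched reads toward mature miRNAs.

    A read counts toward a mature miRNA when it is an exact sense substring
    of the hairpin and its 5' end lies within ``window`` nt of the annotated
    mature 5' end.  Hairpin-level totals (any exact hairpin hit) are kept
    for the abundance panel.  The RPM denominator is the number of
    category-assigned reads per sample unless ``denominators`` is supplied.
    """
    hairpins = ref.categories["miRNA"]
    matures = ref.mature_mirnas
    for _, m in matures.iterrows():
        if m["sequence"] != hairpins[m["hairpin"]][m["start"]:m["end"]]:
            raise ValueError(f"mature {m['name']} not contained in its hairpin")

    samples = list(records.columns)
    mature_counts = pd.DataFrame(0, index=list(matures["name"]), columns=samples)
    hairpin_counts = pd.DataFrame(0, index=list(hairpins), columns=samples)

    by_hairpin = {hp: matures[matures["hairpin"] == hp] for hp in hairpins}
    for seq in records.index:
        row = records.loc[seq]
        for hp_name, hp_seq in hairpins.items():
            pos = hp_seq.find(seq)
            if pos == -1:
                continue
            hairpin_counts.loc[hp_name] += row
            while pos != -1:
                hit = None
                for _, m in by_hairpin[hp_name].iterrows():
                    if abs(pos - m["start"]) <= window:
                        hit = m["name"]
                        break
                if hit is not None:
                    mature_counts.loc[hit] += row
                    break
                pos = hp_seq.find(seq, pos + 1)
            break   # a read is attributed to one hairpin only

    if denominators is None:
        assigned = assignments["category"] != "unassigned"
        denominators = records.loc[assignments.index[assigned]].sum(axis=0).astype(float)
    denominators = denominators.reindex(samples)
    rpm = mature_counts * 1e6 / denominators.replace(0, np.nan)
    matrix = ExpressionMatrix(
        rpm=rpm.fillna(0.0),
        counts=mature_counts,
        hairpin_counts=hairpin_counts,
        denominators=denominators,
    )
    matrix.validate()
    return matrix


def filter_low(rpm: pd.DataFrame, threshold_rpm: float = RPM_THRESHOLD) -> pd.DataFrame:
    """Keep miRNAs reaching ``threshold_rpm`` (inclusive) in >= 1 sample."""
    keep = (rpm >= threshold_rpm).any(axis=1)
    return rpm.loc[keep]


def fold_change(
    rpm: pd.DataFrame, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-fraction log2((RPM_7-8h + c) / (RPM_0-1h + c)) with c = 10 reads.

    Expects sample columns named ``{stage}_{fraction}`` for both stages;
    the UF column is reported as ``Tot``.
    """
    if (rpm.values < 0).any():
        raise ValueError("negative RPM")
    early, late = STAGES
    out = {}
    for frac, col in [("UF", "Tot"), ("mRNP", "mRNP"), ("60S", "60S"),
                      ("80S", "80S"), ("Poly", "Poly")]:
        a, b = f"{early}_{frac}", f"{late}_{frac}"
        if a not in rpm.columns or b not in rpm.columns:
            raise ValueError(f"missing sample column {a!r} or {b!r}")
        out[col] = np.log2((rpm[b] + pseudocount) / (rpm[a] + pseudocount))
    fc = pd.DataFrame(out)[list(FC_COLUMNS)]
    fc.index.name = "miRNA"
    return fc


def classify_groups(fc: pd.DataFrame, tau: float = TAU) -> pd.Series:
    """Assign each miRNA to one of the four polysome-association groups.

    See the module docstring for the rule.  Thresholds are inclusive.
    """
    for col in FC_COLUMNS:
        if col not in fc.columns:
            raise ValueError(f"missing fold-change column {col!r}")
    groups = {}
    for mirna, row in fc.iterrows():
        tot = row["Tot"]
        if abs(tot) < tau:
            groups[mirna] = "G2"
            continue
        d = 1.0 if tot > 0 else -1.0
        vals = row[list(FRACTION_COLUMNS)].astype(float)
        support = (d * vals >= tau).any()
        opposition = (-d * vals >= tau).any()
        if not support and opposition:
            groups[mirna] = "G4"
        else:
            groups[mirna] = "G1" if d > 0 else "G3"
    out = pd.Series(groups, name="group")
    out.index.name = "miRNA"
    return out


def abundance_panel(
    hairpin_shares: pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Union of each sample's top-``k`` hairpins, with per-sample coverage.

    ``hairpin_shares`` holds per-sample hairpin percentages (columns sum to
    100 over hairpins).  Returns ``(panel, coverage)``: the share table
    restricted to the panel, and the total share the panel captures in each
    sample.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    members: list[str] = []
    for col in hairpin_shares.columns:
        for name in hairpin_shares[col].nlargest(k).index:
            if name not in members:
                members.append(name)
    panel = hairpin_shares.loc[members]
    return panel, panel.sum(axis=0)


def hairpin_shares(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample percentage of hairpin-matched reads per hairpin."""
    counts = matrix.hairpin_counts.astype(float)
    totals = counts.sum(axis=0).replace(0, np.nan)
    return (counts / totals * 100.0).fillna(0.0)


def fraction_distribution(rpm: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each miRNA across the four fractions, per stage.

    Returns a DataFrame with MultiIndex columns (stage, fraction); each
    (miRNA, stage) row block sums to 100.  miRNAs absent from all four
    fractions of a stage are undefined (NaN) and listed in
    ``result.attrs["undefined"]``.
    """
    blocks, undefined = {}, []
    for stage in STAGES:
        cols = [f"{stage}_{f}" for f in FRACTION_COLUMNS]
        missing = [c for c in cols if c not in rpm.columns]
        if missing:
            raise ValueError(f"missing fraction samples {missing}")
        sub = rpm[cols].astype(float)
        totals = sub.sum(axis=1)
        zero = totals == 0
        undefined.extend((m, stage) for m in sub.index[zero])
        pct = sub.div(totals.replace(0, np.nan), axis=0) * 100.0
        for frac, col in zip(FRACTION_COLUMNS, cols):
            blocks[(stage, frac)] = pct[col]
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stage", "fraction"])
    out.attrs["undefined"] = undefined
    return out


@dataclass
class CosedimentationReport:
    distances: pd.DataFrame          # pairwise Euclidean, square form
    linkage: np.ndarray              # complete-linkage tree
    newick: str
    within_mean: float
    between_mean: float
    separation: float                # within_mean - between_mean
    undefined: bool


def cluster_cosedimentation(
    distributions: pd.DataFrame, mirna_clusters: pd.Series
) -> CosedimentationReport:
    """Compare fraction-distribution vectors within vs between genomic clusters.

    ``distributions`` holds one fraction-distribution vector per miRNA (rows);
    ``mirna_clusters`` maps miRNA name to genomic cluster id.  Distances are
    Euclidean; the dendrogram uses complete linkage.  The summary statistic
    is mean within-cluster minus mean between-cluster distance (negative
    when cluster members co-sediment).  With fewer than two clusters of two
    or more members the summary is flagged undefined.
    """
    data = distributions.dropna()
    names = list(data.index)
    if len(names) < 2:
        raise ValueError("need at least two miRNAs with defined distributions")
    dist = pdist(data.values, metric="euclidean")
    square = pd.DataFrame(squareform(dist), index=names, columns=names)
    Z = hierarchy.linkage(dist, method="complete")
    newick = _to_newick(Z, names)

    labels = mirna_clusters.reindex(names)
    within, between = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = square.iloc[i, j]
            if labels.iloc[i] == labels.iloc[j] and pd.notna(labels.iloc[i]):
                within.append(d)
            else:
                between.append(d)
    multi = labels.value_counts()
    undefined = (multi >= 2).sum() < 2 or not within or not between
    w = float(np.mean(within)) if within else float("nan")
    b = float(np.mean(between)) if between else float("nan")
    return CosedimentationReport(
        distances=square, linkage=Z, newick=newick,
        within_mean=w, between_mean=b, separation=w - b, undefined=undefined,
    )


def _to_newick(Z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.4g},{right}:{node.dist / 2:.4g})"

    return walk(tree) + ";"


def editing_candidates(
    records: pd.DataFrame,
    ref: ReferenceSet,
    min_fraction: float = 0.1,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Detect single-substitution variants of mature miRNA sequences.

    Reads of the same length as a mature miRNA that differ from it at
    exactly one position are aggregated by (miRNA, 1-based position,
    ref base, alt base); candidates must reach ``min_reads`` supporting
    reads and a supporting fraction of ``min_fraction`` among that miRNA's
    exact + variant reads.  From short reads alone an RNA editing event is
    indistinguishable from a genomic SNP, which the output notes.
    """
    matures = ref.mature_mirnas
    exact_counts = {
        m["name"]: int(records.loc[m["sequence"]].sum())
        if m["sequence"] in records.index else 0
        for _, m in matures.iterrows()
    }
    agg: dict[tuple, int] = {}
    for seq in records.index:
        total = int(records.loc[seq].sum())
        for _, m in matures.iterrows():
            mat = m["sequence"]
            if len(seq) != len(mat) or seq == mat:
                continue
            diffs = [i for i, (a, b) in enumerate(zip(mat, seq)) if a != b]
            if len(diffs) == 1:
                i = diffs[0]
                key = (m["name"], i + 1, mat[i], seq[i])
                agg[key] = agg.get(key, 0) + total
    rows = []
    for (name, pos, ref_base, alt), support in sorted(agg.items()):
        denom = support + exact_counts[name]
        frac = support / denom if denom else 0.0
        if support >= min_reads and frac >= min_fraction:
            rows.append({
                "miRNA": name, "position": pos, "ref": ref_base, "alt": alt,
                "supporting_reads": support, "fraction": frac,
                "note": "SNP vs editing not distinguishable from reads alone",
            })
    return pd.DataFrame(
        rows,
        columns=["miRNA", "position", "ref", "alt",
                 "supporting_reads", "fraction", "note"],
    )


def load_polysome_table() -> pd.DataFrame:
    """Published log2 fold-change table of 94 mature miRNAs.

    Columns: miRNA, Tot, mRNP, 60S, 80S, Poly and the published group label
    G; index is the miRNA name.  Fold changes compare 7-8 h to 0-1 h
    polysome-fractionated embryos.
    """
    path = resources.files("srnafrac.data") / "dme_mirna_polysome_log2fc.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("miRNA")
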