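"""eCLIP peak k-mer analysis.

Prepares bound/unbound sequence sets for downstream motif modeling
(peaks extended 20 nt upstream, same-length negative windows taken 300 nt
upstream, 50-nt folding-context flanks), profiles 5-mer frequencies per
experiment, clusters experiments by Pearson correlation of those profiles
with centroid linkage, and locates the rank of a known IUPAC motif among
frequency-ranked 5-mers.

"Upstream" is strand-aware throughout (the 5' direction of the annotated
strand): eCLIP libraries are strand-specific, so minus-strand peaks are
extracted as the reverse complement with upstream on the high-coordinate
side.  BED intervals are 0-based half-open.  Sequences are emitted as DNA
(T); the k-mer counters treat T and U identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import kmers

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "U", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PeakSet:
    """Peak intervals from one eCLIP experiment (BED6, 0-based half-open)."""

    intervals: list[tuple[str, int, int, str]]  # (chrom, start, end, strand)
    experiment_id: str = ""
    protein: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end, strand in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path, **meta) -> "PeakSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": int, "end": int, "strand": str},
        )
        intervals = list(
            zip(df["chrom"], df["start"].astype(int), df["end"].astype(int), df["strand"])
        )
        return cls(intervals, **meta)


@dataclass
class SequenceRecord:
    """One prepared sequence: binding core plus folding-context flanks."""

    name: str
    chrom: str
    start: int  # core coordinates (0-based half-open, + strand reference)
    end: int
    strand: str
    core: str  # peak + 20-nt upstream extension (sense strand)
    with_context: str  # core with 50-nt flanks on both sides


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    return str(genome[chrom][start:end]).upper()


def prepare_priesstess_inputs(
    peaks: PeakSet,
    genome,
    upstream_ext: int = 20,
    neg_offset: int = 300,
    flank: int = 50,
) -> tuple[list[SequenceRecord], list[SequenceRecord], int]:
    """Positive/negative sequence sets for motif-model training.

    Each peak is extended ``upstream_ext`` nt upstream (strand-aware) to
    make sure the crosslink-adjacent binding site is included; the
    matched negative is the same-length window whose sequence starts
    ``neg_offset`` nt upstream of the extended peak.  Both carry
    ``flank``-nt context on each side (intended to be stripped after RNA
    folding).  Windows falling off a chromosome end are dropped and
    counted.  Returns (positives, negatives, n_dropped).
    """
    import pyfaidx

    if isinstance(genome, (str, bytes)):
        genome = pyfaidx.Fasta(str(genome))
    chrom_len = {name: len(genome[name]) for name in genome.keys()}
    positives: list[SequenceRecord] = []
    negatives: list[SequenceRecord] = []
    dropped = 0
    for i, (chrom, start, end, strand) in enumerate(peaks.intervals):
        if chrom not in chrom_len:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if strand == "+":
            core = (start - upstream_ext, end)
            neg = (core[0] - neg_offset, core[1] - neg_offset)
        else:
            core = (start, end + upstream_ext)
            neg = (core[0] + neg_offset, core[1] + neg_offset)
        records = []
        ok = True
        for kind, (cs, ce) in (("pos", core), ("neg", neg)):
            fs, fe = cs - flank, ce + flank
            if fs < 0 or fe > chrom_len[chrom]:
                ok = False
                break
            core_seq = _fetch(genome, chrom, cs, ce)
            full_seq = _fetch(genome, chrom, fs, fe)
            if strand == "-":
                core_seq = revcomp(core_seq)
                full_seq = revcomp(full_seq)
            records.append(
                SequenceRecord(
                    name=f"{peaks.experiment_id or 'peak'}_{i}_{kind}",
                    chrom=chrom,
                    start=cs,
                    end=ce,
                    strand=strand,
                    core=core_seq,
                    with_context=full_seq,
                )
            )
        if not ok:
            dropped += 1
            continue
        positives.append(records[0])
        negatives.append(records[1])
    return positives, negatives, dropped


def write_fasta(records: Sequence[SequenceRecord], path, context: bool = True) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.name} {r.chrom}:{r.start}-{r.end}({r.strand})\n")
            fh.write((r.with_context if context else r.core) + "\n")


def count_5mers(sequences: Sequence[str], k: int = 5) -> np.ndarray:
    """Frequency vector over all 4^k k-mers across peak sequences.

    Windows containing ambiguous bases (N etc.) are skipped; windows never
    span sequence boundaries.  Frequencies sum to 1.
    """
    counts = kmers.count_kmers(sequences, k)
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable k-mer windows in the input sequences")
    return counts / total


@dataclass
class ClusterResult:
    corr: np.ndarray  # (n, n) Pearson matrix of the retained experiments
    linkage: np.ndarray  # scipy linkage matrix (centroid, distance 1 - r)
    labels: np.ndarray  # flat cluster labels
    kept: list[int]  # indices of experiments passing the peak filter
    excluded: list[int]


def correlate_and_cluster(
    profiles: Sequence[np.ndarray],
    peak_counts: Sequence[int] | None = None,
    min_peaks: int = 1000,
    n_clusters: int = 2,
) -> ClusterResult:
    """All-by-all Pearson correlation and centroid-linkage clustering.

    Experiments with fewer than ``min_peaks`` peaks are excluded (and
    reported) before correlating; agglomeration runs on distance 1 - r.
    """
    n = len(profiles)
    if peak_counts is None:
        kept = list(range(n))
    else:
        kept = [i for i in range(n) if peak_counts[i] >= min_peaks]
    excluded = sorted(set(range(n)) - set(kept))
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 experiments after the {min_peaks}-peak filter, "
            f"have {len(kept)}"
        )
    X = np.stack([np.asarray(profiles[i], dtype=float) for i in kept])
    corr = np.corrcoef(X)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(len(kept), k=1)]
    Z = hierarchy.linkage(condensed, method="centroid")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterResult(corr, Z, labels, kept, excluded)


def linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{0.0:.6f}"
        left, right = rec(node.left), rec(node.right)
        return f"({left},{right}):{node.dist:.6f}"

    return rec(tree) + ";"


def plot_correlation_heatmap(result: ClusterResult, names: Sequence[str], path) -> None:
    """Clustered correlation heatmap (leaf-ordered rows/columns)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(result.linkage)
    C = result.corr[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(order)),) * 2)
    im = ax.imshow(C, vmin=-1, vmax=1, cmap="RdBu_r")
    labels = [names[result.kept[i]] for i in order]
    ax.set_xticks(range(len(order)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r (5-mer frequencies)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def iupac_rank(profile: np.ndarray, iupac: str, k: int = 5):
    """1-based frequency rank of the first k-mer matching an IUPAC motif.

    Observed k-mers (frequency > 0) are ranked by descending frequency
    (ties broken lexicographically); a k-mer matches if it equals some
    length-k contiguous window of the IUPAC pattern with every position's
    base in that IUPAC code's set.  Returns ``None`` when no observed
    k-mer matches ("absent").
    """
    iupac = iupac.upper()
    if len(iupac) < k:
        raise ValueError(f"IUPAC motif must be at least {k} long")
    bad = set(iupac) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols: {sorted(bad)}")
    profile = np.asarray(profile, dtype=float)
    if profile.size != 4**k:
        raise ValueError(f"profile must have length 4^{k}")
    # allowed base codes per window position, for every length-k window
    windows = [iupac[i : i + k] for i in range(len(iupac) - k + 1)]
    allowed = [
        [frozenset(kmers.RNA_BASES.index(b) for b in IUPAC[sym]) for sym in w]
        for w in windows
    ]
    order = np.lexsort((np.arange(profile.size), -profile))
    order = order[profile[order] > 0]
    for rank, code in enumerate(order, start=1):
        digits = [(int(code) >> shift) & 3 for shift in range(2 * (k - 1), -2, -2)]
        for win in allowed:
            if all(d in s for d, s in zip(digits, win)):
                return rank
    return None
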