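"""Position frequency matrices from top-scoring 7-mers.

A motif is derived by stacking the ten highest-Z 7-mers: each is aligned
ungapped to the top 7-mer at the offset (within +/-3) that maximizes
position-wise identity, contributes its bases weighted by max(Z, 0), and
the resulting count matrix is pseudocounted, trimmed of uninformative
flanks, and column-normalized.  Information content per column is
2 + sum_b p_b log2 p_b bits against a uniform background.  Motif-motif
similarity is the mean per-column Pearson correlation of probability
vectors at the best ungapped offset, with an empirical p-value from
seeded column-shuffled nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import RNA_BASES, encode
from .scoring import KmerTable

PSEUDOCOUNT = 0.01
IC_TRIM_BITS = 0.1
OFFSET_RANGE = 3
MIN_OVERLAP = 4


@dataclass
class PFM:
    """Position frequency matrix over (A, C, G, U), one row per position."""

    matrix: np.ndarray  # (L, 4), rows sum to 1
    name: str = ""
    support: int = 0  # number of weighted k-mers aggregated

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PFM matrix must be (L, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PFM entries must be nonnegative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self.matrix.argmax(axis=1))

    # -- I/O ---------------------------------------------------------------

    def to_meme(self, path) -> None:
        """Minimal MEME motif format (RNA alphabet)."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
            fh.write("Background letter frequencies\n")
            fh.write("A 0.25 C 0.25 G 0.25 U 0.25\n\n")
            fh.write(f"MOTIF {self.name or 'motif'}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(self)} "
                f"nsites= {max(self.support, 1)} E= 0\n"
            )
            for row in self.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")

    @classmethod
    def from_meme(cls, path) -> "PFM":
        rows: list[list[float]] = []
        name = ""
        in_matrix = False
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s.startswith("MOTIF"):
                    name = s.split(maxsplit=1)[1] if " " in s else ""
                elif s.startswith("letter-probability matrix"):
                    in_matrix = True
                elif in_matrix:
                    if not s:
                        break
                    rows.append([float(x) for x in s.split()])
        if not rows:
            raise ValueError(f"no letter-probability matrix found in {path}")
        return cls(np.array(rows), name=name)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, columns=list(RNA_BASES)).to_csv(
            path, sep="\t", index_label="position"
        )


def information_content(pfm: PFM) -> tuple[float, np.ndarray]:
    """(total bits, per-position bits) against a uniform background."""
    p = pfm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p), 0.0)
    per_col = 2.0 + term.sum(axis=1)
    return float(per_col.sum()), per_col


def _best_offset(kmer_codes: np.ndarray, anchor_codes: np.ndarray, max_offset: int) -> int:
    """Ungapped offset of ``kmer`` against ``anchor`` maximizing identity.

    Ties prefer the smallest |offset|, then the negative one.
    """
    best = None
    for off in sorted(range(-max_offset, max_offset + 1), key=lambda o: (abs(o), o)):
        ident = 0
        for j in range(kmer_codes.size):
            a = j + off
            if 0 <= a < anchor_codes.size and kmer_codes[j] == anchor_codes[a]:
                ident += 1
        if best is None or ident > best[0]:
            best = (ident, off)
    return best[1]


def build_motif(
    table: KmerTable,
    n_top: int = 10,
    pseudocount: float = PSEUDOCOUNT,
    ic_trim: float = IC_TRIM_BITS,
    max_offset: int = OFFSET_RANGE,
    trim: bool = True,
    name: str = "",
) -> PFM:
    """PFM from the ``n_top`` highest-Z k-mers of a score table.

    Each k-mer is aligned to the top k-mer and stacked with weight
    max(Z, 0), so anti-enriched k-mers never contribute.  If every weight
    is zero (a pathological flat experiment) the stack falls back to
    uniform weights so a well-formed, if uninformative, PFM is still
    returned.  Flanking positions with information content below
    ``ic_trim`` bits are trimmed unless ``trim`` is False.
    """
    top, z = table.top(n_top)
    if len(top) < n_top or not np.isfinite(z).all():
        raise ValueError(f"need {n_top} k-mers with finite Z, got {len(top)}")
    k = table.universe.k
    weights = np.maximum(z, 0.0)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    anchor = encode(top[0])
    width = k + 2 * max_offset
    counts = np.zeros((width, 4))
    for kmer, w in zip(top, weights):
        codes = encode(kmer)
        off = _best_offset(codes, anchor, max_offset)
        for j, c in enumerate(codes):
            counts[max_offset + off + j, c] += w
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    if trim:
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = 2.0 + np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=1)
        informative = np.flatnonzero(ic >= ic_trim)
        if informative.size:
            probs = probs[informative.min() : informative.max() + 1]
        else:
            # nothing informative: keep the core k positions
            probs = probs[max_offset : max_offset + k]
    return PFM(probs, name=name, support=n_top)


# ---------------------------------------------------------------------------
# motif-motif comparison


def _unit_columns(matrix: np.ndarray) -> np.ndarray:
    """Center each position's 4-vector and scale to unit norm.

    Constant (e.g. uniform) positions become zero vectors, contributing a
    correlation of 0 wherever they overlap.
    """
    c = matrix - matrix.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    out = np.zeros_like(c)
    np.divide(c, norm, out=out, where=norm > 0)
    return out


def _offset_pairs(lp: int, lq: int, min_overlap: int):
    """Yield (offset, p-indices, q-indices) for all ungapped alignments.

    Offset o places q so its position j aligns with p position j + o.
    """
    for o in range(-(lq - min_overlap), lp - min_overlap + 1):
        ip = np.arange(max(0, o), min(lp, lq + o))
        iq = ip - o
        if ip.size >= min_overlap:
            yield o, ip, iq


def compare_motifs(
    p: PFM,
    q: PFM,
    n_null: int = 1000,
    seed: int = 0,
    min_overlap: int = MIN_OVERLAP,
) -> tuple[float, int, float]:
    """(similarity, best offset, empirical p-value) of two PFMs.

    Similarity is the mean per-position Pearson correlation of the
    probability 4-vectors at the best ungapped offset with at least
    ``min_overlap`` overlapping positions.  The p-value is the fraction of
    column-shuffled nulls scoring at least as high, averaged over
    shuffling q's columns and shuffling p's columns so the comparison is
    symmetric.
    """
    lp, lq = len(p), len(q)
    if min(lp, lq) < min_overlap:
        raise ValueError(
            f"motifs of lengths {lp} and {lq} cannot overlap by {min_overlap}"
        )
    up, uq = _unit_columns(p.matrix), _unit_columns(q.matrix)
    rmat = up @ uq.T  # (lp, lq) all pairwise position correlations

    alignments = list(_offset_pairs(lp, lq, min_overlap))
    scores = np.array([rmat[ip, iq].mean() for _, ip, iq in alignments])
    order = sorted(
        range(len(alignments)),
        key=lambda i: (-scores[i], abs(alignments[i][0]), alignments[i][0]),
    )
    best_i = order[0]
    best_score = float(scores[best_i])
    best_offset = int(alignments[best_i][0])

    if n_null <= 0:
        return best_score, best_offset, float("nan")

    def null_fraction(r: np.ndarray, l_shuffled: int, axis: int) -> float:
        # fresh identically-seeded RNG per orientation: the permutations
        # used to shuffle a given motif are then independent of argument
        # order, making the p-value exactly symmetric
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_null, l_shuffled)), axis=1)
        best = np.full(n_null, -np.inf)
        for _, ip, iq in alignments:
            if axis == 1:  # shuffle q columns
                vals = r[ip[:, None], perms[:, iq].T].mean(axis=0)
            else:  # shuffle p columns
                vals = r[perms[:, ip].T, iq[:, None]].mean(axis=0)
            np.maximum(best, vals, out=best)
        return float((best >= best_score - 1e-12).mean())

    pval = 0.5 * (null_fraction(rmat, lq, axis=1) + null_fraction(rmat, lp, axis=0))
    return best_score, best_offset, pval


# ---------------------------------------------------------------------------
# logo rendering


def plot_logo(pfm: PFM, path=None, ax=None, title: str | None = None):
    """Render a sequence logo (letter heights = p * column IC, in bits)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    _, per_col = information_content(pfm)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(0.5 * len(pfm) + 1, 2.2))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for i, (row, ic) in enumerate(zip(pfm.matrix, per_col)):
        y = 0.0
        for b in np.argsort(row):  # draw small letters first, stack upward
            h = row[b] * ic
            if h <= 1e-3:
                continue
            letter = RNA_BASES[b]
            tp = TextPath((0, 0), letter, size=1, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(i + 0.05, y)
            )
            ax.add_patch(PathPatch(tp.transformed(tr), color=colors[letter], lw=0))
            y += h
    ax.set_xlim(0, len(pfm))
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(len(pfm)) + 0.5)
    ax.set_xticklabels(np.arange(1, len(pfm) + 1))
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    if own_fig:
        if path is None:
            raise ValueError("provide a path or an axes")
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
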