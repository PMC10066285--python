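"""Designed RNA pool construction.

The pool emulates the classic designed (non-random) RNA competition pool:
a single order-11 de Bruijn cycle over {A,C,G,U} is chopped into 241,399
probes of 30-41 nt and split computationally into two halves, Set A and
Set B, such that every scored 7-mer (all 16,384 minus the two SapI-site
7-mers) occurs at least 155 times in each half.  The overlap between
consecutive probe windows is kept at >= 10 nt so every 11-mer window of
the cycle survives in at least one probe, which in turn guarantees every
9-mer keeps at least its cyclic multiplicity of 16 across probes.

The de Bruijn cycle is built as a seeded Eulerian circuit on the graph
whose nodes are (order-1)-mers; the published pool's post-hoc secondary
structure minimization is not reproduced (the procedure is unpublished),
but an optional hairpin screen hook is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import kmers
from .kmers import KmerUniverse, code_to_kmer, decode, default_universe, encode

PHI25_PROMOTER = "TAATACGACTCACTATT"
INITIATORS = ("AGA", "AGG")
DEFAULT_PROBE_COUNT = 241_399
DEFAULT_MIN_PER_SET = 155
MAX_DEBRUIJN_ORDER = 12  # 4^12 = 16.7M symbols; beyond this refuse to allocate


class PoolDesignError(ValueError):
    """A pool design constraint cannot be met with the given parameters."""


class CapacityError(PoolDesignError):
    """The requested de Bruijn order exceeds the configured memory bound."""


# ---------------------------------------------------------------------------
# de Bruijn cycle


def generate_debruijn(
    order: int,
    alphabet: str = "ACGU",
    seed: int = 0,
    max_order: int = MAX_DEBRUIJN_ORDER,
) -> np.ndarray:
    """Seeded de Bruijn cycle of the given order over a 4-letter alphabet.

    Returns the cyclic sequence as a uint8 code array of length 4^order in
    which every length-``order`` word occurs exactly once when read
    cyclically.  Construction: Eulerian circuit on the (order-1)-mer graph
    (nodes = (order-1)-mers, 4 out-edges each) with the edge order at every
    node drawn from a seeded RNG, via iterative Hierholzer traversal.
    Deterministic function of ``(order, seed)``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(set(alphabet)) != 4:
        raise ValueError("alphabet must contain exactly 4 distinct symbols")
    if order > max_order:
        raise CapacityError(
            f"order {order} needs 4^{order} = {4**order:,} symbols, above the "
            f"configured bound (order <= {max_order})"
        )
    rng = np.random.default_rng(seed)
    if order == 1:
        # trivial cycle: each symbol exactly once, in seeded order
        return rng.permutation(4).astype(np.uint8)
    n_nodes = 4 ** (order - 1)
    mask = n_nodes - 1
    perms = rng.permuted(
        np.tile(np.arange(4, dtype=np.int8), (n_nodes, 1)), axis=1
    )
    pflat = perms.ravel().tolist()
    ptr = bytearray(n_nodes)
    stack = [0]
    circuit: list[int] = []
    push = stack.append
    pop = stack.pop
    emit = circuit.append
    while stack:
        v = stack[-1]
        p = ptr[v]
        if p < 4:
            ptr[v] = p + 1
            c = pflat[(v << 2) | p]
            push(((v << 2) | c) & mask)
        else:
            emit(pop())
    circuit.reverse()
    # circuit lists 4^order + 1 nodes; each transition contributes one symbol
    nodes = np.array(circuit[1:], dtype=np.int64)
    seq = (nodes & 3).astype(np.uint8)
    if seq.size != 4**order:
        raise RuntimeError("Eulerian traversal did not cover every edge")
    return seq


def debruijn_str(order: int, seed: int = 0, rna: bool = True) -> str:
    """Convenience: the seeded de Bruijn cycle as a string."""
    return decode(generate_debruijn(order, seed=seed), rna=rna)


# ---------------------------------------------------------------------------
# probe pool container


class ProbePool:
    """A designed probe library: sequences plus optional Set A/B labels.

    Parameters
    ----------
    ids, sequences:
        Parallel lists; ids must be unique, sequences are RNA over ACGU.
    set_labels:
        Optional array of 'A'/'B' labels, one per probe.
    design_meta:
        Free-form provenance (de Bruijn order, seeds, window schedule).
    """

    def __init__(
        self,
        ids: Sequence[str],
        sequences: Sequence[str],
        set_labels: Sequence[str] | None = None,
        design_meta: dict | None = None,
    ) -> None:
        self.ids = list(ids)
        self.sequences = list(sequences)
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("probe ids are not unique")
        if set_labels is not None:
            set_labels = np.asarray(set_labels, dtype="<U1")
            if set_labels.shape != (len(self.ids),):
                raise ValueError("set_labels length mismatch")
            bad = set(np.unique(set_labels)) - {"A", "B"}
            if bad:
                raise ValueError(f"invalid set labels: {sorted(bad)}")
        self.set_labels = set_labels
        self.design_meta = dict(design_meta or {})
        self._cache: dict = {}

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        lab = "unlabeled" if self.set_labels is None else "A/B labeled"
        return f"ProbePool({len(self)} probes, {lab})"

    @property
    def probe_lengths(self) -> np.ndarray:
        out = self._cache.get("lengths")
        if out is None:
            out = np.fromiter(
                (len(s) for s in self.sequences), count=len(self), dtype=np.int64
            )
            self._cache["lengths"] = out
        return out

    def codes(self) -> list[np.ndarray]:
        """Per-probe uint8 code arrays (cached; validates the alphabet)."""
        out = self._cache.get("codes")
        if out is None:
            out = []
            for pid, s in zip(self.ids, self.sequences):
                c = encode(s)
                if c.size and c.max() >= kmers.SENTINEL:
                    raise ValueError(f"probe {pid} contains non-ACGU characters")
                out.append(c)
            self._cache["codes"] = out
        return out

    def window_index(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(window k-mer codes, owning probe index) across all probes."""
        key = ("windex", k)
        if key not in self._cache:
            self._cache[key] = kmers.pooled_window_index(self.codes(), k)
        return self._cache[key]

    def unique_pairs(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Distinct (k-mer code, probe index) pairs: probe presence, not
        multiplicity — a probe supports a k-mer once however often it
        contains it."""
        key = ("pairs", k)
        if key not in self._cache:
            wcodes, wprobe = self.window_index(k)
            keyed = wprobe.astype(np.int64) * (4**k) + wcodes
            uniq = np.unique(keyed)
            self._cache[key] = (uniq % (4**k), (uniq // (4**k)).astype(np.int32))
        return self._cache[key]

    def subset_mask(self, subset: str) -> np.ndarray:
        if subset == "merged":
            return np.ones(len(self), dtype=bool)
        if subset in ("A", "B"):
            if self.set_labels is None:
                raise ValueError("pool has no Set A/B labels")
            return self.set_labels == subset
        raise ValueError(f"subset must be 'A', 'B' or 'merged', got {subset!r}")

    def kmer_counts(self, k: int, subset: str = "merged") -> np.ndarray:
        """Overlapping k-mer occurrence counts across the probes of a subset."""
        wcodes, wprobe = self.window_index(k)
        mask = self.subset_mask(subset)
        return np.bincount(wcodes[mask[wprobe]], minlength=4**k)

    def id_index(self) -> dict[str, int]:
        out = self._cache.get("id_index")
        if out is None:
            out = {pid: i for i, pid in enumerate(self.ids)}
            self._cache["id_index"] = out
        return out

    def with_labels(self, set_labels: Sequence[str]) -> "ProbePool":
        new = ProbePool(self.ids, self.sequences, set_labels, self.design_meta)
        # sequence-derived caches remain valid
        for key, val in self._cache.items():
            if key != "id_index":
                new._cache[key] = val
        return new

    # -- I/O ---------------------------------------------------------------

    def to_fasta(self, path) -> None:
        records = (
            SeqRecord(Seq(s), id=pid, description="")
            for pid, s in zip(self.ids, self.sequences)
        )
        SeqIO.write(records, path, "fasta")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "probe_id": self.ids,
                "set_label": (
                    self.set_labels
                    if self.set_labels is not None
                    else [""] * len(self)
                ),
                "length": self.probe_lengths,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path, tsv_path=None) -> "ProbePool":
        ids, seqs = [], []
        for rec in SeqIO.parse(fasta_path, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper().replace("T", "U"))
        labels = None
        if tsv_path is not None:
            df = pd.read_csv(tsv_path, sep="\t", dtype={"probe_id": str})
            lab = dict(zip(df["probe_id"], df["set_label"].fillna("")))
            if any(lab.get(pid) for pid in ids):
                labels = [lab[pid] for pid in ids]
        return cls(ids, seqs, labels)


# ---------------------------------------------------------------------------
# chopping the cycle into probes


def default_window_schedule(
    seed: int = 0,
    n: int = 257,
    min_len: int = 30,
    max_len: int = 41,
    preserve_m: int = 11,
) -> list[tuple[int, int]]:
    """Seeded (length, step) schedule with the maximum coverage-preserving
    step per window: step = length - preserve_m + 1, so consecutive windows
    overlap by preserve_m - 1 and every preserve_m-window of the cycle
    lands inside some probe."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return [(int(l), int(l - preserve_m + 1)) for l in lengths]


def chop_pool(
    cycle: np.ndarray | str,
    target_count: int,
    window_schedule: Sequence[tuple[int, int]] | None = None,
    preserve_m: int = 11,
    seed: int = 0,
    id_prefix: str = "probe",
) -> ProbePool:
    """Tile a cyclic sequence into exactly ``target_count`` probes.

    Two interleaved tilings are used.  The first applies the (length, step)
    schedule cyclically around the whole cycle; because every step obeys
    step <= length - preserve_m + 1, every ``preserve_m``-window of the
    cycle (including those crossing the origin) is contained in at least
    one probe.  The second tiling, offset from the first, contributes the
    remaining probes at an evenly spaced stride and is truncated so the
    total is exactly ``target_count``.
    """
    codes = encode(cycle) if isinstance(cycle, str) else np.asarray(cycle, np.uint8)
    L = codes.size
    if L == 0:
        raise ValueError("empty cycle")
    if window_schedule is None:
        window_schedule = default_window_schedule(seed, preserve_m=preserve_m)
    for length, step in window_schedule:
        if length < preserve_m:
            raise PoolDesignError(
                f"window length {length} shorter than preserve_m={preserve_m}"
            )
        if step < 1:
            raise PoolDesignError(f"step {step} must be >= 1")
        if step > length - preserve_m + 1:
            raise PoolDesignError(
                f"step {step} > length {length} - preserve_m {preserve_m} + 1: "
                f"an occurrence of some {preserve_m}-mer would be lost"
            )
        if length > L:
            raise PoolDesignError(f"window length {length} exceeds cycle length {L}")

    starts: list[int] = []
    lens: list[int] = []
    pos = 0
    i = 0
    m = len(window_schedule)
    while pos < L:
        length, step = window_schedule[i % m]
        starts.append(pos)
        lens.append(length)
        pos += step
        i += 1
    n1 = len(starts)
    if target_count < n1:
        raise PoolDesignError(
            f"schedule tiles the cycle with {n1} probes but target_count is "
            f"{target_count}; achievable counts are {n1}..{n1 + L}"
        )
    deficit = target_count - n1
    if deficit > L:
        raise PoolDesignError(
            f"cannot reach {target_count} probes: at most {n1 + L} achievable"
        )
    if deficit:
        stride = L // deficit
        offset = window_schedule[0][1] // 2
        for j in range(deficit):
            starts.append((offset + j * stride) % L)
            lens.append(window_schedule[j % m][0])

    max_len = max(lens)
    cyc = decode(codes)
    ext = cyc + cyc[:max_len]
    width = len(str(target_count))
    ids = [f"{id_prefix}_{j:0{width}d}" for j in range(target_count)]
    seqs = [ext[s : s + l] for s, l in zip(starts, lens)]
    meta = {
        "cycle_length": L,
        "preserve_m": preserve_m,
        "window_schedule": list(window_schedule),
        "chop_seed": seed,
        "target_count": target_count,
        "first_tiling_count": n1,
    }
    return ProbePool(ids, seqs, design_meta=meta)


# ---------------------------------------------------------------------------
# Set A / Set B split


def split_sets(
    pool: ProbePool,
    universe: KmerUniverse,
    min_per_set: int = DEFAULT_MIN_PER_SET,
    seed: int = 0,
    max_rounds: int = 50,
) -> ProbePool:
    """Split the pool into Set A and Set B with per-k-mer guarantees.

    Every k-mer of the scoring universe must end up with at least
    ``min_per_set`` occurrences in each set.  Initial assignment
    alternates probes between sets (consecutive probes tile overlapping
    regions of the cycle, so this splits each k-mer's occurrences nearly
    evenly); violations are then repaired by greedily moving probes from
    the surplus set, never moving a probe whose departure would push any
    of its own k-mers below the floor.
    """
    k = universe.k
    wcodes, wprobe = pool.window_index(k)
    n = len(pool)
    umask = universe.member_mask
    total = np.bincount(wcodes, minlength=4**k)
    short = np.flatnonzero(umask & (total < 2 * min_per_set))
    if short.size:
        worst = [(code_to_kmer(c, k), int(total[c])) for c in short[:10]]
        raise PoolDesignError(
            f"{short.size} universe {k}-mers occur fewer than 2*min_per_set="
            f"{2 * min_per_set} times in the pool, e.g. {worst}"
        )

    assign = (np.arange(n) % 2).astype(np.int8)  # 0 -> A, 1 -> B
    counts = np.zeros((2, 4**k), dtype=np.int64)
    for s in (0, 1):
        counts[s] = np.bincount(wcodes[assign[wprobe] == s], minlength=4**k)

    # per-probe window CSR (wprobe is sorted by construction)
    indptr = np.searchsorted(wprobe, np.arange(n + 1))
    # inverted index: windows of each k-mer code
    order = np.argsort(wcodes, kind="stable")
    code_ptr = np.searchsorted(wcodes[order], np.arange(4**k + 1))

    def probe_codes(p: int) -> tuple[np.ndarray, np.ndarray]:
        pc = wcodes[indptr[p] : indptr[p + 1]]
        return np.unique(pc, return_counts=True)

    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        deficits = [
            (s, int(c))
            for s in (0, 1)
            for c in np.flatnonzero(umask & (counts[s] < min_per_set))
        ]
        if not deficits:
            break
        moved_any = False
        for s, w in deficits:
            if counts[s, w] >= min_per_set:
                continue
            t = 1 - s
            cand = np.unique(wprobe[order[code_ptr[w] : code_ptr[w + 1]]])
            cand = cand[assign[cand] == t]
            cand = cand[rng.permutation(cand.size)]
            for p in cand:
                if counts[s, w] >= min_per_set:
                    break
                uniq, mult = probe_codes(int(p))
                sel = umask[uniq]
                if np.all(counts[t, uniq[sel]] - mult[sel] >= min_per_set):
                    counts[t, uniq] -= mult
                    counts[s, uniq] += mult
                    assign[p] = s
                    moved_any = True
        if not moved_any:
            break

    bad = [
        (code_to_kmer(c, k), "AB"[s], int(counts[s, c]))
        for s in (0, 1)
        for c in np.flatnonzero(umask & (counts[s] < min_per_set))
    ]
    if bad:
        raise PoolDesignError(
            f"set split could not reach min_per_set={min_per_set} for "
            f"{len(bad)} (k-mer, set) pairs after repair, e.g. {bad[:10]}"
        )
    labels = np.where(assign == 0, "A", "B")
    out = pool.with_labels(labels)
    out.design_meta.update({"split_seed": seed, "min_per_set": min_per_set})
    return out


# ---------------------------------------------------------------------------
# DNA template side


def add_t7_prefix(
    pool: ProbePool,
    initiator: str = "AGA",
    promoter: str = PHI25_PROMOTER,
) -> list[tuple[str, str]]:
    """DNA template pool: phi2.5 T7 promoter + initiator + DNA transliteration.

    The promoter/initiator prefix exists only on the DNA template used for
    in-vitro transcription; RNA-side analyses never see it.
    """
    if initiator not in INITIATORS:
        raise ValueError(f"initiator must be one of {INITIATORS}, got {initiator!r}")
    prefix = promoter + initiator
    return [(pid, prefix + s.replace("U", "T")) for pid, s in zip(pool.ids, pool.sequences)]


def strip_t7_prefix(
    template: str, promoter: str = PHI25_PROMOTER
) -> str:
    """Inverse of :func:`add_t7_prefix`: recover the RNA probe sequence."""
    for initiator in INITIATORS:
        prefix = promoter + initiator
        if template.startswith(prefix):
            return template[len(prefix) :].replace("T", "U")
    raise ValueError("template does not start with the promoter+initiator prefix")


def write_template_fasta(templates: list[tuple[str, str]], path) -> None:
    records = (SeqRecord(Seq(s), id=pid, description="") for pid, s in templates)
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# optional hairpin screen (disabled by default; see module docstring)


def max_selfcomp_stem(seq: str, min_loop: int = 3) -> int:
    """Length of the longest Watson-Crick self-complementary stem in a probe.

    A crude hairpin screen: the longest run s.t. seq[i..i+m) pairs with the
    reverse complement of seq[j..j+m) for some j >= i + m + min_loop.
    Quadratic; intended for spot checks, not the full pool.
    """
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    rc = "".join(comp[b] for b in reversed(seq))
    n = len(seq)
    best = 0
    # longest common substring between seq and its reverse complement;
    # min_loop is ignored in this coarse screen (over-estimates stems).
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


# ---------------------------------------------------------------------------
# end-to-end builds


def build_default_pool(
    seed: int = 0,
    order: int = 11,
    target_count: int = DEFAULT_PROBE_COUNT,
    min_per_set: int = DEFAULT_MIN_PER_SET,
    universe: KmerUniverse | None = None,
    window_schedule: Sequence[tuple[int, int]] | None = None,
) -> ProbePool:
    """Full default design: order-11 cycle, 241,399 probes, balanced split.

    Deterministic given ``seed`` (sub-seeds for the cycle, the window
    schedule, and the split are derived from it).
    """
    if universe is None:
        universe = default_universe(7)
    rng = np.random.default_rng(seed)
    s_cycle, s_chop, s_split = (int(x) for x in rng.integers(0, 2**31, size=3))
    cycle = generate_debruijn(order, seed=s_cycle)
    pool = chop_pool(cycle, target_count, window_schedule, seed=s_chop)
    pool = split_sets(pool, universe, min_per_set=min_per_set, seed=s_split)
    pool.design_meta.update({"debruijn_order": order, "seed": seed})
    return pool


def build_reduced_pool(seed: int = 0, target_count: int = 15_000) -> ProbePool:
    """Simulation-scale design: order-9 cycle, ~15k probes, floor of 5
    occurrences of every scored 7-mer per set.  Same construction as the
    full design, scaled so a simulated experiment scores in well under a
    second."""
    return build_default_pool(
        seed=seed, order=9, target_count=target_count, min_per_set=5
    )


# ---------------------------------------------------------------------------
# YAML design config


@dataclass
class PoolDesignConfig:
    """Tunable constants of the default design, loadable from YAML."""

    order: int = 11
    target_count: int = DEFAULT_PROBE_COUNT
    min_per_set: int = DEFAULT_MIN_PER_SET
    min_len: int = 30
    max_len: int = 41
    preserve_m: int = 11
    promoter: str = PHI25_PROMOTER
    excluded_kmers: tuple[str, ...] = kmers.DEFAULT_EXCLUDED_7MERS

    @classmethod
    def from_yaml(cls, path) -> "PoolDesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "excluded_kmers" in raw:
            raw["excluded_kmers"] = tuple(raw["excluded_kmers"])
        return cls(**raw)

    def universe(self) -> KmerUniverse:
        return KmerUniverse(k=7, excluded=frozenset(self.excluded_kmers))
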