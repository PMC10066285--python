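"""Probe intensities to per-set 7-mer Z-scores.

The quantitative core: probe-level fluorescence intensities are
log-transformed and median-centered, and each scored 7-mer receives the
trimmed mean (2.5% per tail by default) of the normalized intensities of
the probes that contain it — a probe counts once per 7-mer regardless of
multiplicity, since its intensity is a single measurement.  Scores are
standardized robustly: Z = (score - median) / (1.4826 * MAD), computed
over the scoring universe, so the Z distribution has median 0 and unit
robust scale whenever the MAD is positive.  Under a standard normal null,
Z > 5 corresponds to a Bonferroni-corrected one-sided P below 0.005
across the 16,382 scored 7-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import KmerUniverse, code_to_kmer, default_universe
from .pool import ProbePool

MAD_CONSISTENCY = 1.4826  # robust SD estimate under normality
DEFAULT_TRIM = 0.025


@dataclass
class IntensityProfile:
    """One experiment's probe-level intensities with exclusion flags."""

    probe_ids: list[str]
    values: np.ndarray
    usable: np.ndarray  # True = usable, False = excluded (flagged) spot
    normalized: bool = False  # log-scale values may be negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if not (len(self.probe_ids) == self.values.size == self.usable.size):
            raise ValueError("probe_ids, values and usable must be parallel")
        v = self.values[self.usable]
        if v.size and not np.isfinite(v).all():
            raise ValueError("usable intensities must be finite")
        if not self.normalized and v.size and (v < 0).any():
            raise ValueError("raw intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "intensity": self.values,
                "flag": (~self.usable).astype(int),  # 0 usable, 1 excluded
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IntensityProfile":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
        flag = df["flag"] if "flag" in df else pd.Series(0, index=df.index)
        return cls(
            list(df["probe_id"]),
            df["intensity"].to_numpy(float),
            flag.to_numpy(int) == 0,
        )


def normalize_intensities(profile: IntensityProfile) -> IntensityProfile:
    """Drop excluded probes, log-transform, and median-center.

    The transform is rank-preserving on the usable probes and leaves the
    output median at exactly 0 on the log scale.  Zero intensities are
    clipped to half the smallest positive usable intensity before the log
    (fluorescence of zero is below the quantification floor, not a true
    zero).
    """
    keep = profile.usable
    if not keep.any():
        raise ValueError("all probes are excluded; nothing to normalize")
    v = profile.values[keep]
    pos = v[v > 0]
    floor = (pos.min() / 2.0) if pos.size else 1.0
    logv = np.log(np.maximum(v, floor))
    logv -= np.median(logv)
    ids = [pid for pid, u in zip(profile.probe_ids, keep) if u]
    return IntensityProfile(ids, logv, np.ones(logv.size, dtype=bool), normalized=True)


@dataclass
class KmerTable:
    """Trimmed-mean scores and Z-scores over a scoring universe."""

    subset: str  # 'A', 'B' or 'merged'
    universe: KmerUniverse
    scores: np.ndarray  # aligned with universe.member_codes
    zscores: np.ndarray
    n_probes: int = 0

    def __post_init__(self) -> None:
        m = self.universe.member_codes.size
        if self.scores.size != m or self.zscores.size != m:
            raise ValueError("score arrays must align with the universe members")

    def z(self, kmer: str) -> float:
        from .kmers import kmer_to_code

        idx = np.searchsorted(self.universe.member_codes, kmer_to_code(kmer))
        if (
            idx >= self.universe.member_codes.size
            or self.universe.member_codes[idx] != kmer_to_code(kmer)
        ):
            raise KeyError(f"{kmer} is not in the scoring universe")
        return float(self.zscores[idx])

    def top(self, n: int = 10) -> tuple[list[str], np.ndarray]:
        """Top-n k-mers by Z, descending; ties broken lexicographically."""
        # member_codes are sorted, so code order == lexicographic order
        order = np.lexsort((self.universe.member_codes, -self.zscores))[:n]
        kmers_ = [code_to_kmer(self.universe.member_codes[i], self.universe.k) for i in order]
        return kmers_, self.zscores[order]

    def as_dataframe(self) -> pd.DataFrame:
        k = self.universe.k
        return pd.DataFrame(
            {
                "kmer": [code_to_kmer(c, k) for c in self.universe.member_codes],
                "score": self.scores,
                "zscore": self.zscores,
            }
        )


def _grouped_trimmed_means(
    codes: np.ndarray,
    values: np.ndarray,
    member_codes: np.ndarray,
    trim_fraction: float,
) -> np.ndarray:
    """Vectorized per-k-mer trimmed means.

    ``codes``/``values`` are parallel (k-mer code, probe value) pairs; the
    result is aligned with ``member_codes``.  Raises if any member code has
    no supporting pair.
    """
    n_codes = int(member_codes[-1]) + 1 if member_codes.size else 0
    cnt = np.bincount(codes, minlength=n_codes)
    missing = member_codes[cnt[member_codes] == 0]
    if missing.size:
        raise ValueError(
            f"{missing.size} universe k-mers have no supporting probe in this "
            f"subset (pool/universe mismatch), e.g. code {int(missing[0])}"
        )
    order = np.lexsort((values, codes))
    sv = values[order]
    cs = np.concatenate(([0.0], np.cumsum(sv)))
    starts = np.concatenate(([0], np.cumsum(cnt)))
    n = cnt[member_codes]
    t = np.floor(n * trim_fraction).astype(np.int64)
    lo = starts[member_codes] + t
    hi = starts[member_codes] + n - t
    denom = (n - 2 * t).astype(float)
    if (denom <= 0).any():
        raise ValueError("trim_fraction removes every observation for some k-mer")
    return (cs[hi] - cs[lo]) / denom


def robust_z(scores: np.ndarray) -> np.ndarray:
    """Median/MAD standardization with the 1.4826 consistency factor.

    If the MAD is zero the standard deviation is used instead; if that is
    also zero every Z is 0.
    """
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    scale = MAD_CONSISTENCY * mad
    if scale == 0:
        scale = scores.std()
    if scale == 0:
        return np.zeros_like(scores)
    return (scores - med) / scale


def compute_kmer_zscores(
    profile: IntensityProfile,
    pool: ProbePool,
    subset: str = "merged",
    universe: KmerUniverse | None = None,
    trim_fraction: float = DEFAULT_TRIM,
) -> KmerTable:
    """Per-k-mer trimmed-mean scores and robust Z-scores for one subset.

    ``profile`` should be normalized (see :func:`normalize_intensities`);
    probes absent from the profile (e.g. flagged spots) simply do not
    contribute.  Every universe k-mer must retain at least one supporting
    probe in the subset.
    """
    if universe is None:
        universe = default_universe(7)
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    idx = pool.id_index()
    vals = np.full(len(pool), np.nan)
    present = np.zeros(len(pool), dtype=bool)
    for pid, v, u in zip(profile.probe_ids, profile.values, profile.usable):
        if u and pid in idx:
            vals[idx[pid]] = v
            present[idx[pid]] = True
    mask = pool.subset_mask(subset) & present
    if not mask.any():
        raise ValueError(f"no usable probes in subset {subset!r}")
    pair_codes, pair_probes = pool.unique_pairs(universe.k)
    sel = mask[pair_probes]
    codes = pair_codes[sel]
    values = vals[pair_probes[sel]]
    scores = _grouped_trimmed_means(
        codes, values, universe.member_codes, trim_fraction
    )
    return KmerTable(
        subset=subset,
        universe=universe,
        scores=scores,
        zscores=robust_z(scores),
        n_probes=int(mask.sum()),
    )


def bonferroni_tail(z: float, n_tests: int) -> float:
    """Bonferroni-corrected one-sided upper-tail normal probability."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(1.0, n_tests * stats.norm.sf(z)))


def ab_diagnostics(table_a: KmerTable, table_b: KmerTable, n_top: int = 10) -> tuple[float, int]:
    """Set A vs Set B reproducibility: Z-score Pearson r and top-N overlap."""
    ua, ub = table_a.universe, table_b.universe
    if ua.k != ub.k or set(ua.excluded) != set(ub.excluded):
        raise ValueError("tables were computed over different universes")
    za, zb = table_a.zscores, table_b.zscores
    if za.std() == 0 or zb.std() == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(za, zb).statistic)
    top_a, _ = table_a.top(n_top)
    top_b, _ = table_b.top(n_top)
    return r, len(set(top_a) & set(top_b))


def score_experiment(
    profile: IntensityProfile,
    pool: ProbePool,
    universe: KmerUniverse | None = None,
    trim_fraction: float = DEFAULT_TRIM,
) -> dict[str, KmerTable]:
    """Normalize once and score Set A, Set B, and the merged pool.

    The merged table is recomputed from the union of probes, not averaged
    from the per-set tables.
    """
    norm = normalize_intensities(profile)
    return {
        s: compute_kmer_zscores(norm, pool, s, universe, trim_fraction)
        for s in ("A", "B", "merged")
    }


def zscore_table_tsv(tables: dict[str, KmerTable], path) -> None:
    """Write the combined per-7-mer score table, sorted by merged Z."""
    dfa = tables["A"].as_dataframe().rename(columns={"score": "scoreA", "zscore": "zA"})
    dfb = tables["B"].as_dataframe().rename(columns={"score": "scoreB", "zscore": "zB"})
    dfm = tables["merged"].as_dataframe().rename(columns={"zscore": "zMerged"})
    out = dfa.merge(dfb, on="kmer").merge(dfm[["kmer", "zMerged"]], on="kmer")
    out.sort_values(["zMerged", "kmer"], ascending=[False, True]).to_csv(
        path, sep="\t", index=False
    )
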