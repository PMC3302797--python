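"""Adjacent-pair linkage disequilibrium (delta-squared) with distance binning.

LD between neighboring SNPs is measured as Δ² = D²/(p(1-p)q(1-q)) on the
haploid (inbred homozygote) frequencies of complete-case accessions, the
squared correlation of the 0/1-coded call vectors (ρ²/r² for inbred lines).
"Neighboring" means consecutive in map order on the same chromosome; pairs
further apart than ``max_kb`` (default 2000 kb) are excluded. Pair means are
summarized per 50-kb distance bin, by default over pairs in "complete LD"
(0 < Δ² < 1), with the counts of Δ²=0 and Δ²=1 pairs reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix


def delta_squared(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Δ² for one SNP pair over complete-case accessions.

    Returns NaN (undefined) when fewer than 2 complete observations remain
    or either SNP is monomorphic among them.
    """
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    ok = (calls_i != MISSING) & (calls_j != MISSING)
    if ok.sum() < 2:
        return float("nan")
    a = calls_i[ok] == 0
    b = calls_j[ok] == 0
    p = a.mean()
    q = b.mean()
    denom = p * (1 - p) * q * (1 - q)
    if denom == 0:
        return float("nan")
    x = (a & b).mean()
    d = x - p * q
    return float(d * d / denom)


@dataclass(frozen=True)
class LdPair:
    snp_i: str
    snp_j: str
    chromosome: int
    distance_bp: int
    delta_sq: float
    n_complete: int


def ld_pairs(matrix: GenotypeMatrix, group_rows: np.ndarray,
             max_kb: float = 2000.0) -> pd.DataFrame:
    """Δ² for every consecutive same-chromosome SNP pair within ``max_kb``."""
    placed = matrix.snps.dropna(subset=["chromosome", "position_bp"])
    chrom = placed["chromosome"].to_numpy(dtype=np.int64)
    pos = placed["position_bp"].to_numpy(dtype=np.int64)
    cols = placed.index.to_numpy()
    sub = matrix.calls[group_rows, :]
    rows = []
    for k in range(len(cols) - 1):
        if chrom[k] != chrom[k + 1]:
            continue
        dist = int(pos[k + 1] - pos[k])
        if dist > max_kb * 1000:
            continue
        ci = sub[:, cols[k]]
        cj = sub[:, cols[k + 1]]
        n_complete = int(((ci != MISSING) & (cj != MISSING)).sum())
        rows.append((placed["snp_id"].iloc[k], placed["snp_id"].iloc[k + 1],
                     int(chrom[k]), dist, delta_squared(ci, cj), n_complete))
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "chromosome",
                                       "distance_bp", "delta_sq", "n_complete"])


def ld_profile(matrix: GenotypeMatrix, group_rows: np.ndarray,
               bin_kb: float = 50.0, max_kb: float = 2000.0,
               complete_only: bool = True) -> pd.DataFrame:
    """Mean adjacent-pair Δ² per distance bin.

    Bins are left-open right-closed multiples of ``bin_kb`` anchored at 0:
    (0,50], (50,100], ... A pair at exactly a bin edge falls in the lower
    bin. With ``complete_only`` (the default) the bin mean is restricted to
    pairs in complete LD, 0 < Δ² < 1; pairs at exactly 0 or 1 are counted in
    ``n_zero``/``n_one`` but excluded from the mean. ``complete_only=False``
    averages all defined Δ² values instead.
    """
    pairs = ld_pairs(matrix, group_rows, max_kb=max_kb)
    n_bins = int(np.ceil(max_kb / bin_kb))
    out = []
    if len(pairs):
        dist_kb = pairs["distance_bp"].to_numpy() / 1000.0
        bin_idx = np.ceil(dist_kb / bin_kb).astype(int)  # (0,50] -> 1
        bin_idx = np.clip(bin_idx, 1, None)
        d2 = pairs["delta_sq"].to_numpy()
    for b in range(1, n_bins + 1):
        if len(pairs):
            sel = bin_idx == b
            vals = d2[sel]
            defined = vals[~np.isnan(vals)]
        else:
            defined = np.array([])
        n_zero = int((defined == 0).sum())
        n_one = int((defined == 1).sum())
        if complete_only:
            use = defined[(defined > 0) & (defined < 1)]
        else:
            use = defined
        out.append({"bin_low_kb": (b - 1) * bin_kb, "bin_high_kb": b * bin_kb,
                    "n_pairs": int(defined.size),
                    "n_zero": n_zero, "n_one": n_one,
                    "n_used": int(use.size),
                    "mean_delta_sq": float(use.mean()) if use.size else float("nan")})
    return pd.DataFrame(out)


def plot_ld_profiles(profiles: dict[str, pd.DataFrame], path) -> None:
    """Diagnostic figure: mean Δ² per 50-kb bin per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for group, prof in profiles.items():
        mid = (prof["bin_low_kb"] + prof["bin_high_kb"]) / 2
        ax.plot(mid, prof["mean_delta_sq"], marker=".", label=group)
    ax.set_xlabel("distance between adjacent SNPs (kb)")
    ax.set_ylabel("mean $\\Delta^2$ (0 < $\\Delta^2$ < 1)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
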