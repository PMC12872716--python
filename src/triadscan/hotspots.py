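"""Genomic-region scan for clusters of concordant differential expression.

Per-gene log2 fold changes are smoothed along each chromosome with
Nadaraya-Watson local kernel regression (Gaussian kernel in base-pair
space, evaluated at gene midpoints), positional significance is assessed
against a genome-wide permutation null (or an analytic one-sample t
approximation), p-values are FDR-corrected with Benjamini-Hochberg, and
maximal runs of significant, direction-consistent genes are merged into
hotspot regions.

Genes absent from the DEG contrast enter with log2FC 0 so the whole
annotated gene set serves as the background.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "smooth_statistic",
    "HotspotScan",
    "HotspotScanResult",
    "call_regions",
    "regions_to_bed",
]

DEFAULT_BANDWIDTH = 10e6   # bp; wheat-scale chromosomes
DEFAULT_N_PERM = 10_000
DEFAULT_Q_CUTOFF = 1e-5


def _kernel_weights(positions: np.ndarray, bandwidth: float) -> np.ndarray:
    """Row-normalised Gaussian kernel weight matrix over gene midpoints."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d = (positions[:, None] - positions[None, :]) / bandwidth
    w = np.exp(-0.5 * d * d)
    return w / w.sum(axis=1, keepdims=True)


def smooth_statistic(positions, log2fc, bandwidth_bp: float) -> np.ndarray:
    """Nadaraya-Watson kernel smoothing of per-gene log2FC in bp space."""
    positions = np.asarray(positions, dtype=float)
    y = np.asarray(log2fc, dtype=float)
    if positions.size != y.size:
        raise ValueError("positions and log2fc must align")
    if positions.size == 1:
        # single-gene chromosome: smoothing degenerates to the gene itself
        return y.copy()
    return _kernel_weights(positions, bandwidth_bp) @ y


def _jitter_positions(positions: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Break midpoint ties deterministically with a gene-id hash (< 1 bp)."""
    pos = positions.astype(float).copy()
    _, inverse, counts = np.unique(pos, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        jit = np.array([(zlib.crc32(g.encode()) % 997) / 997.0 - 0.5
                        for g in gene_ids])
        pos[dup] += jit[dup] * 0.9
    return pos


@dataclass
class HotspotScanResult:
    """Per-position statistics plus region calling for one contrast."""
    contrast: str
    mode: str
    bandwidth: float
    n_perm: int
    table: pd.DataFrame  # gene_id, chrom, pos, start, end, log2fc, smoothed,
                         # p_up, p_down, q_up, q_down
    def regions(self, q_cutoff: float = DEFAULT_Q_CUTOFF) -> pd.DataFrame:
        return call_regions(self.table, q_cutoff)

    def summary(self, q_cutoff: float = DEFAULT_Q_CUTOFF) -> str:
        reg = self.regions(q_cutoff)
        lines = [
            f"Hotspot scan: contrast={self.contrast} mode={self.mode} "
            f"bandwidth={self.bandwidth:g} bp n_perm={self.n_perm}",
            f"positions={len(self.table)} chromosomes="
            f"{self.table['chrom'].nunique()} q_cutoff={q_cutoff:g}",
            f"regions called: {len(reg)} "
            f"(up={int((reg['direction'] == 'up').sum())}, "
            f"down={int((reg['direction'] == 'down').sum())})",
        ]
        return "\n".join(lines)


class HotspotScan:
    """Positional enrichment scan of one DEG contrast over an annotation.

    Parameters
    ----------
    annotation : DataFrame with gene_id, chrom, start, end (1-based closed).
    degs : DEG table; rows of other contrasts are ignored, annotated genes
        missing from the contrast contribute log2FC 0.
    contrast : contrast label to scan.
    bandwidth : Gaussian kernel bandwidth in bp.
    mode : 'permutation' (genome-wide label permutation null, default) or
        't' (kernel-weighted one-sample t with Satterthwaite effective n).
    n_perm : permutations for the null (p floored at 1/(n_perm+1)).
    """

    def __init__(self, annotation: pd.DataFrame, degs: pd.DataFrame, contrast: str,
                 bandwidth: float = DEFAULT_BANDWIDTH, mode: str = "permutation",
                 n_perm: int = DEFAULT_N_PERM):
        if mode not in ("permutation", "t"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "permutation" and n_perm < 1000:
            raise ValueError("permutation mode requires n_perm >= 1000")
        self.annotation = annotation.reset_index(drop=True)
        self.contrast = contrast
        self.bandwidth = float(bandwidth)
        self.mode = mode
        self.n_perm = int(n_perm)
        sub = degs[degs["contrast"] == contrast] if "contrast" in degs else degs
        lfc = sub.set_index("gene_id")["log2fc"]
        if lfc.index.has_duplicates:
            raise ValueError(f"duplicate genes in contrast {contrast!r}")
        self._lfc = (self.annotation["gene_id"].map(lfc)
                     .fillna(0.0).to_numpy(dtype=float))

    def fit(self, seed: int | None = 0) -> HotspotScanResult:
        ann = self.annotation
        mid = ((ann["start"] + ann["end"]) / 2.0).to_numpy()
        table = ann[["gene_id", "chrom", "start", "end"]].copy()
        table["log2fc"] = self._lfc
        table["pos"] = np.nan
        for col in ("smoothed", "p_up", "p_down"):
            table[col] = np.nan

        chrom_index: dict[str, np.ndarray] = {}
        order_parts = []
        for chrom in pd.unique(ann["chrom"]):
            idx = np.flatnonzero((ann["chrom"] == chrom).to_numpy())
            pos = _jitter_positions(mid[idx], ann["gene_id"].to_numpy()[idx])
            sort = np.argsort(pos, kind="stable")
            idx = idx[sort]
            chrom_index[chrom] = idx
            table.loc[idx, "pos"] = pos[sort]
            order_parts.append(idx)

        weights = {c: _kernel_weights(table.loc[i, "pos"].to_numpy(), self.bandwidth)
                   if len(i) > 1 else np.ones((1, 1))
                   for c, i in chrom_index.items()}
        y = self._lfc
        smoothed = np.empty_like(y)
        for c, idx in chrom_index.items():
            smoothed[idx] = weights[c] @ y[idx]
        table["smoothed"] = smoothed

        if self.mode == "permutation":
            p_up, p_down = self._permutation_p(chrom_index, weights, smoothed, seed)
        else:
            p_up, p_down = self._analytic_p(chrom_index, weights, y)
        table["p_up"], table["p_down"] = p_up, p_down
        table["q_up"] = multipletests(p_up, method="fdr_bh")[1]
        table["q_down"] = multipletests(p_down, method="fdr_bh")[1]

        order = np.concatenate(order_parts)
        table = table.loc[order].reset_index(drop=True)
        return HotspotScanResult(contrast=self.contrast, mode=self.mode,
                                 bandwidth=self.bandwidth, n_perm=self.n_perm,
                                 table=table)

    # -- null models ------------------------------------------------------

    def _permutation_p(self, chrom_index, weights, smoothed, seed,
                       chunk: int = 500):
        """Genome-wide permutation of log2FC over gene positions."""
        rng = np.random.default_rng(seed)
        y = self._lfc
        n = y.size
        ge = np.zeros(n, dtype=np.int64)  # null >= observed
        le = np.zeros(n, dtype=np.int64)  # null <= observed
        done = 0
        while done < self.n_perm:
            m = min(chunk, self.n_perm - done)
            perm = np.empty((n, m))
            for j in range(m):
                perm[:, j] = y[rng.permutation(n)]
            for c, idx in chrom_index.items():
                null = weights[c] @ perm[idx]
                obs = smoothed[idx][:, None]
                ge[idx] += (null >= obs).sum(axis=1)
                le[idx] += (null <= obs).sum(axis=1)
            done += m
        p_up = (1.0 + ge) / (self.n_perm + 1.0)
        p_down = (1.0 + le) / (self.n_perm + 1.0)
        return p_up, p_down

    def _analytic_p(self, chrom_index, weights, y):
        """Kernel-weighted one-sample t against 0, Satterthwaite-style n_eff."""
        n = y.size
        p_up = np.ones(n)
        p_down = np.ones(n)
        for c, idx in chrom_index.items():
            w = weights[c]
            yy = y[idx]
            m = w @ yy
            var = np.maximum(w @ (yy * yy) - m * m, 0.0)  # kernel-weighted variance
            n_eff = 1.0 / np.maximum((w * w).sum(axis=1), 1e-300)
            df = np.maximum(n_eff - 1.0, 1e-6)
            denom = w.sum(axis=1) - (w * w).sum(axis=1)  # reliability-weight corr.
            with np.errstate(divide="ignore", invalid="ignore"):
                s2 = var * w.sum(axis=1) / np.maximum(denom, 1e-300)
                t = m / np.sqrt(s2 / n_eff)
            degenerate = ~np.isfinite(t) | (s2 <= 0)  # all-equal neighbourhood
            t = np.where(degenerate, 0.0, t)
            p_up[idx] = np.where(degenerate, 1.0, sps.t.sf(t, df))
            p_down[idx] = np.where(degenerate, 1.0, sps.t.cdf(t, df))
        return p_up, p_down


def call_regions(table: pd.DataFrame, q_cutoff: float = DEFAULT_Q_CUTOFF
                 ) -> pd.DataFrame:
    """Merge maximal runs of consecutive significant same-direction genes.

    Region bounds are the min start / max end of member genes.
    """
    rows = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        direction = np.where(sub["q_up"] < q_cutoff, "up",
                             np.where(sub["q_down"] < q_cutoff, "down", ""))
        i = 0
        vals = sub.reset_index(drop=True)
        while i < len(vals):
            if direction[i] == "":
                i += 1
                continue
            j = i
            while j + 1 < len(vals) and direction[j + 1] == direction[i]:
                j += 1
            run = vals.iloc[i:j + 1]
            qcol = "q_up" if direction[i] == "up" else "q_down"
            peak = run.loc[run["smoothed"].abs().idxmax(), "smoothed"]
            rows.append({
                "chrom": chrom,
                "start": int(run["start"].min()),
                "end": int(run["end"].max()),
                "direction": direction[i],
                "peak_statistic": float(peak),
                "min_q": float(run[qcol].min()),
                "n_genes": len(run),
            })
            i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "peak_statistic", "min_q", "n_genes"])


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED (0-based half-open) with direction and q columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, row in enumerate(regions.itertuples(index=False), start=1):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\thotspot_{k}\t0\t.\t"
                     f"{row.direction}\t{row.min_q:.3g}\t{row.n_genes}\n")
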