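"""Genotype-matrix I/O, quality filtering and imputation.

The filtering ladder follows GBS practice for RIL panels: markers whose
missing rate exceeds a threshold (``mpm``) are dropped, then monomorphic
markers, then markers with minor allele frequency below ``maf_min``
(computed on non-missing calls, heterozygotes contributing one allele
copy); samples whose missing rate exceeds ``mps`` are filtered afterwards.
Imputation fills the remaining holes so downstream whole-genome regression
receives a complete matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rilgs.matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping of what each filtering rule removed."""

    thresholds: dict = field(default_factory=dict)
    markers_in: int = 0
    removed_missing: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    samples_in: int = 0
    removed_samples: int = 0
    skipped_multiallelic: int = 0
    warnings: list = field(default_factory=list)

    @property
    def markers_out(self) -> int:
        return (
            self.markers_in
            - self.removed_missing
            - self.removed_monomorphic
            - self.removed_maf
        )

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.removed_samples

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "markers_in": self.markers_in,
            "removed_missing": self.removed_missing,
            "removed_monomorphic": self.removed_monomorphic,
            "removed_maf": self.removed_maf,
            "markers_out": self.markers_out,
            "samples_in": self.samples_in,
            "removed_samples": self.removed_samples,
            "samples_out": self.samples_out,
            "skipped_multiallelic": self.skipped_multiallelic,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_GT_CODE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def read_vcf(path, populations: dict | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Read a VCF with GT fields into an allele-dose matrix.

    Only biallelic SNP records are kept; multiallelic records are skipped
    and counted in the report. Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2 and ./. -> missing. ``populations`` optionally maps sample id
    to a population label (default: "pop").
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"VCF not found: {path}")
    except ValueError as exc:
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    report = FilterReport(samples_in=len(samples))
    rows, meta = [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            report.skipped_multiallelic += 1
            continue
        row = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            row[i] = _GT_CODE.get(tuple(gt), np.nan)
        rows.append(row)
        mid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
        meta.append((mid, rec.chrom, rec.pos))
    vcf.close()
    report.markers_in = len(rows)
    if report.skipped_multiallelic:
        log.info("skipped %d multiallelic records", report.skipped_multiallelic)
    values = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    pops = np.array([populations.get(s, "pop") if populations else "pop" for s in samples])
    return GenotypeMatrix(values, np.array(samples), pops, markers), report


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF v4.2 text file (GT only, ./. missing)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in G.line_ids)
            + "\n"
        )
        for j, (_, mk) in enumerate(G.markers.iterrows()):
            gts = "\t".join(
                code.get(v, "./.") if not np.isnan(v) else "./."
                for v in G.values[:, j]
            )
            fh.write(f"{mk['chrom']}\t{mk['pos']}\t{mk['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_markers(
    G: GenotypeMatrix, mpm: float = 0.2, maf_min: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers by missing rate, monomorphism, then MAF — in that order."""
    if not 0.0 <= mpm <= 1.0:
        raise ValueError("mpm must lie in [0, 1]")
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    report = FilterReport(
        thresholds={"mpm": mpm, "maf_min": maf_min},
        markers_in=G.n_markers,
        samples_in=G.n_lines,
    )
    keep = np.ones(G.n_markers, dtype=bool)
    miss = G.missing_rate_per_marker()
    bad = miss > mpm
    report.removed_missing = int(bad.sum())
    keep &= ~bad
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        std = np.nanstd(G.values, axis=0)
        maf = G.minor_allele_freq()
    mono = keep & ((std == 0) | np.isnan(std))
    report.removed_monomorphic = int(mono.sum())
    keep &= ~mono
    low = keep & (maf < maf_min)
    report.removed_maf = int(low.sum())
    keep &= ~low
    if not keep.any():
        err = ValueError("all markers removed by filtering")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return G.take_markers(np.flatnonzero(keep)), report


def filter_samples(G: GenotypeMatrix, mps: float = 0.25) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop lines whose missing rate exceeds ``mps`` (after marker filtering)."""
    if not 0.0 <= mps <= 1.0:
        raise ValueError("mps must lie in [0, 1]")
    report = FilterReport(
        thresholds={"mps": mps}, markers_in=G.n_markers, samples_in=G.n_lines
    )
    keep = G.missing_rate_per_line() <= mps
    report.removed_samples = int((~keep).sum())
    out = G.take_lines(np.flatnonzero(keep))
    for pop in pd.unique(G.populations):
        n_left = int((out.populations == pop).sum())
        if n_left < 2:
            msg = f"population {pop} reduced to {n_left} line(s)"
            report.warnings.append(msg)
            warnings.warn(msg)
    return out, report


def filter_pipeline(
    G: GenotypeMatrix, mpm: float = 0.2, mps: float = 0.25, maf_min: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Markers first, then samples, iterated to a fixed point.

    Removing high-missing samples lowers some markers' missing rates and
    vice versa, so the marker->sample pass repeats until nothing changes;
    this makes the whole pipeline idempotent at fixed thresholds.
    """
    rep = FilterReport(
        thresholds={"mpm": mpm, "mps": mps, "maf_min": maf_min},
        markers_in=G.n_markers,
        samples_in=G.n_lines,
    )
    current = G
    while True:
        g1, rep_m = filter_markers(current, mpm=mpm, maf_min=maf_min)
        g2, rep_s = filter_samples(g1, mps=mps)
        rep.removed_missing += rep_m.removed_missing
        rep.removed_monomorphic += rep_m.removed_monomorphic
        rep.removed_maf += rep_m.removed_maf
        rep.removed_samples += rep_s.removed_samples
        rep.warnings += rep_m.warnings + rep_s.warnings
        changed = (g2.n_markers, g2.n_lines) != (current.n_markers, current.n_lines)
        current = g2
        if not changed:
            break
    return current, rep


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _mode_per_marker(values: np.ndarray) -> np.ndarray:
    """Most frequent call per marker among {0,1,2}; ties break to the lower code."""
    counts = np.stack([(values == c).sum(axis=0) for c in (0.0, 1.0, 2.0)])
    return np.argmax(counts, axis=0).astype(float)  # argmax takes first (lowest) on ties


def impute(G: GenotypeMatrix, method: str = "knn", k: int = 5, seed=None) -> GenotypeMatrix:
    """Fill missing calls; observed entries are returned bit-for-bit unchanged.

    ``mode``: per-marker most frequent call. ``knn``: for each line with
    holes, find the k nearest lines by mean absolute allele-dose difference
    on shared non-missing markers and take the majority vote among their
    observed calls at each hole (ties and empty votes resolve to the
    marker mode, logged).
    """
    mask = G.missing_mask
    if mask.all(axis=0).any() or mask.all(axis=1).any():
        raise ValueError("a marker or sample is entirely missing; filter first")
    if not mask.any():
        return G
    out = G.copy()
    modes = _mode_per_marker(G.values)
    if method == "mode":
        out.values[mask] = np.broadcast_to(modes, G.values.shape)[mask]
        return out
    if method != "knn":
        raise ValueError(f"unknown imputation method: {method}")
    V = G.values
    n = G.n_lines
    obs = ~mask
    tie_count = 0
    for i in np.flatnonzero(mask.any(axis=1)):
        shared = obs[i][None, :] & obs  # (n, M)
        n_shared = shared.sum(axis=1).astype(float)
        diff = np.abs(np.where(shared, V - V[i], 0.0)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(n_shared > 0, diff / n_shared, np.inf)
        dist[i] = np.inf
        neigh = np.argsort(dist, kind="stable")[:k]
        holes = np.flatnonzero(mask[i])
        for j in holes:
            votes = V[neigh, j]
            votes = votes[~np.isnan(votes)]
            if votes.size == 0:
                out.values[i, j] = modes[j]
                tie_count += 1
                continue
            counts = np.array([(votes == c).sum() for c in (0.0, 1.0, 2.0)])
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            if len(winners) > 1:
                out.values[i, j] = modes[j]
                tie_count += 1
            else:
                out.values[i, j] = float(winners[0])
    if tie_count:
        log.info("knn imputation: %d votes resolved toward the marker mode", tie_count)
    return out
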