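"""Metagene templates and per-gene enrichment amplitudes.

Each gene is represented over a fixed layout: a 5' flank, a body scaled to a
fixed number of bins, and a 3' flank.  A mark's *template* is the across-gene
average of these layouts normalized to mean 1; a gene's *amplitude* for the
mark is the least-squares multiplier of the template that best fits the
gene's own tag-count profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "GeneModel",
    "BinnedProfile",
    "Template",
    "AmplitudeMatrix",
    "bin_gene_profile",
    "bin_counts",
    "build_template",
    "estimate_amplitude",
    "estimate_amplitudes",
    "cv_rmsd",
    "fractional_difference",
    "robustness_report",
]


@dataclass
class GeneModel:
    """A gene's coordinates with candidate start/stop sites.

    Coordinates are 0-based half-open (BED convention).  ``start_sites`` and
    ``stop_sites`` are genomic coordinates; on the minus strand the
    transcription start is the *largest* coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    start_sites: list[int]
    stop_sites: list[int]
    chosen_tss: int | None = None
    chosen_tes: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start_sites or not self.stop_sites:
            raise ValueError("gene needs at least one start and one stop site")
        if self.chosen_tss is None:
            self.chosen_tss = self.start_sites[0]
        if self.chosen_tes is None:
            self.chosen_tes = self.stop_sites[0]
        if self.body_length < 1:
            raise ValueError(f"{self.gene_id}: gene body must be >= 1 bp")

    @property
    def body_length(self) -> int:
        return abs(self.chosen_tes - self.chosen_tss)

    def body_interval(self) -> tuple[int, int]:
        """(left, right) genomic interval of the body, left < right."""
        lo, hi = sorted((self.chosen_tss, self.chosen_tes))
        return lo, hi


@dataclass
class BinnedProfile:
    """Per-gene, per-mark tag counts over [5' flank | scaled body | 3' flank]."""

    gene_id: str
    mark_id: str
    values: np.ndarray
    n_body_bins: int
    flank_bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_body_bins + 2 * self.flank_bins
        if self.values.shape != (expected,):
            raise ValueError(
                f"profile length {self.values.shape} != layout {expected}"
            )


@dataclass
class Template:
    """Mark-specific normalized average profile; mean over all positions is 1."""

    mark_id: str
    values: np.ndarray
    n_body_bins: int
    flank_bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.mean()
        if not np.isclose(m, 1.0, atol=1e-9):
            raise ValueError(f"template mean {m} != 1")


@dataclass
class AmplitudeMatrix:
    """Genes x marks amplitudes with CV(RMSD) diagnostics."""

    amplitudes: pd.DataFrame
    cv_rmsd: pd.DataFrame
    n_body_bins: int
    metadata: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.amplitudes.index)

    @property
    def mark_ids(self) -> list[str]:
        return list(self.amplitudes.columns)


def bin_counts(per_base: np.ndarray, n_bins: int) -> np.ndarray:
    """Scale a per-base count vector to ``n_bins`` bins.

    Longer-than-``n_bins`` vectors are averaged within bins whose edges are
    rounded to whole base pairs (a base split across two bins goes entirely to
    the bin holding its majority).  Shorter vectors have their values repeated
    so every bin is filled.
    """
    per_base = np.asarray(per_base, dtype=float)
    length = per_base.shape[0]
    if length == 0:
        return np.zeros(n_bins)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if length >= n_bins:
        edges = np.floor(np.arange(n_bins + 1) * length / n_bins + 0.5).astype(int)
        # rounding can only collide when length < 2*n_bins; force monotonicity
        edges = np.maximum.accumulate(np.maximum(edges, np.arange(n_bins + 1)))
        edges[-1] = length
        csum = np.concatenate(([0.0], np.cumsum(per_base)))
        widths = np.diff(edges)
        return (csum[edges[1:]] - csum[edges[:-1]]) / widths
    # short gene: repeat base values across bins
    idx = np.floor(np.arange(n_bins) * length / n_bins).astype(int)
    idx = np.clip(idx, 0, length - 1)
    return per_base[idx]


def _per_base_counts(
    tag_positions: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    """Count tag 5' start positions per base over [lo, hi)."""
    counts = np.zeros(hi - lo, dtype=float)
    if tag_positions.size:
        inside = tag_positions[(tag_positions >= lo) & (tag_positions < hi)]
        if inside.size:
            np.add.at(counts, inside - lo, 1.0)
    return counts


def bin_gene_profile(
    tag_positions: np.ndarray,
    gene: GeneModel,
    n_body_bins: int,
    flank_bp: int = 2000,
    flank_bin_bp: int = 1,
    mark_id: str = "",
) -> BinnedProfile:
    """Bin one gene's tag counts into the [flank | body | flank] layout.

    ``tag_positions`` are genomic 5'-end coordinates of tags on the gene's
    chromosome.  Minus-strand genes are reported 5'->3' (vector reversed).
    Flanks are counted per base and optionally aggregated into
    ``flank_bin_bp``-sized bins.
    """
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be divisible by flank_bin_bp")
    tag_positions = np.asarray(tag_positions, dtype=int)
    lo, hi = gene.body_interval()

    window_lo, window_hi = lo - flank_bp, hi + flank_bp
    per_base = _per_base_counts(tag_positions, window_lo, window_hi)
    left = per_base[:flank_bp]
    body = per_base[flank_bp : flank_bp + (hi - lo)]
    right = per_base[flank_bp + (hi - lo) :]

    body_binned = bin_counts(body, n_body_bins)
    flank_bins = flank_bp // flank_bin_bp
    if flank_bin_bp > 1:
        left = left.reshape(flank_bins, flank_bin_bp).mean(axis=1)
        right = right.reshape(flank_bins, flank_bin_bp).mean(axis=1)
    values = np.concatenate([left, body_binned, right])
    if gene.strand == "-":
        values = values[::-1]
    return BinnedProfile(
        gene_id=gene.gene_id,
        mark_id=mark_id,
        values=values,
        n_body_bins=n_body_bins,
        flank_bins=flank_bins,
    )


def build_template(profiles: list[BinnedProfile] | np.ndarray, mark_id: str = "") -> Template:
    """Average profiles position-wise and rescale to overall mean 1."""
    if isinstance(profiles, np.ndarray):
        mat = np.atleast_2d(np.asarray(profiles, dtype=float))
        n_body, flanks = mat.shape[1], 0
    else:
        if not profiles:
            raise ValueError("need at least one profile")
        mat = np.vstack([p.values for p in profiles])
        n_body, flanks = profiles[0].n_body_bins, profiles[0].flank_bins
        mark_id = mark_id or profiles[0].mark_id
    mean = mat.mean(axis=0)
    overall = mean.mean()
    if overall <= 0:
        raise ValueError("degenerate template: aggregate profile is all zero")
    return Template(mark_id=mark_id, values=mean / overall,
                    n_body_bins=n_body, flank_bins=flanks)


def estimate_amplitude(profile: BinnedProfile | np.ndarray, template: Template | np.ndarray) -> float:
    """Closed-form least-squares amplitude: A = sum(y*t) / sum(t^2)."""
    y = profile.values if isinstance(profile, BinnedProfile) else np.asarray(profile, float)
    t = template.values if isinstance(template, Template) else np.asarray(template, float)
    denom = float(np.dot(t, t))
    if denom == 0.0:
        raise ValueError("degenerate template: sum of squares is zero")
    return float(np.dot(y, t) / denom)


def estimate_amplitudes(profiles: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Vectorized amplitudes for a (genes x bins) profile matrix."""
    t = np.asarray(template, float)
    denom = float(np.dot(t, t))
    if denom == 0.0:
        raise ValueError("degenerate template: sum of squares is zero")
    return np.asarray(profiles, float) @ t / denom


def cv_rmsd(profile: BinnedProfile | np.ndarray, template: Template | np.ndarray,
            amplitude: float) -> float:
    """Relative model error: RMSD between profile and A*template, over A."""
    if amplitude <= 0:
        return float("nan")
    y = profile.values if isinstance(profile, BinnedProfile) else np.asarray(profile, float)
    t = template.values if isinstance(template, Template) else np.asarray(template, float)
    resid = y - amplitude * t
    return float(np.sqrt(np.mean(resid**2)) / amplitude)


def fractional_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Difference divided by mean: 2*(a-b)/(a+b); 0 where both are 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, 2.0 * (a - b) / denom, 0.0)
    return out


def robustness_report(
    amplitude_sets: dict[int, pd.DataFrame], reference: int
) -> pd.DataFrame:
    """Compare amplitude estimates across body-bin counts.

    ``amplitude_sets`` maps a bin count to a genes x marks amplitude table;
    ``reference`` names the bin count the others are compared against.  For
    each mark and each non-reference bin count, reports the Spearman
    correlation with the reference amplitudes and the 0/25/50/75/100th
    percentiles of the fractional difference across genes.
    """
    if reference not in amplitude_sets:
        raise ValueError(f"reference bin count {reference} not in amplitude_sets")
    if len(amplitude_sets) < 2:
        raise ValueError("need at least two bin counts to compare")
    ref = amplitude_sets[reference]
    rows = []
    for n_bins, other in amplitude_sets.items():
        if n_bins == reference:
            continue
        other = other.loc[ref.index, ref.columns]
        for mark in ref.columns:
            a = other[mark].to_numpy()
            b = ref[mark].to_numpy()
            if np.allclose(a, a[0]) and np.allclose(b, b[0]):
                rho = 1.0 if np.allclose(a, b) else float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho = float(_stats.spearmanr(a, b).statistic)
            fd = fractional_difference(a, b)
            pct = np.percentile(fd, [0, 25, 50, 75, 100])
            rows.append(
                {
                    "mark": mark,
                    "bins": n_bins,
                    "reference_bins": reference,
                    "spearman": rho,
                    "frac_diff_p0": pct[0],
                    "frac_diff_p25": pct[1],
                    "frac_diff_p50": pct[2],
                    "frac_diff_p75": pct[3],
                    "frac_diff_p100": pct[4],
                }
            )
    return pd.DataFrame(rows)
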