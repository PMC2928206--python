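"""Synthetic gene models, tag profiles and expression with known ground truth.

The generator emulates the statistical structure of histone-mark ChIP-Seq
over genes: each mark has a characteristic spatial template, each gene a
positive amplitude driven partly by a shared latent activity factor, and
log2 expression is a planted function of mono-/bi-/trivalent amplitude
terms plus Gaussian noise.  One mark can be constructed as a *confounded
repressor*: its marginal correlation with expression is cancelled
analytically while its conditional (multivariate) effect stays repressive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .profiles import GeneModel

__all__ = [
    "TemplateShape",
    "MarkSpec",
    "PlantedTerm",
    "GroundTruth",
    "SyntheticDataset",
    "make_gene_models",
    "make_true_template",
    "simulate_amplitudes",
    "simulate_profiles",
    "simulate_tags",
    "simulate_expression",
    "make_confounded_repressor",
    "default_scenario",
    "planted_three_term_scenario",
    "hinge_scenario",
]

_POSITIVE_FLOOR = 1e-6


class TemplateShape(str, Enum):
    TSS_PEAK = "tss_peak"
    BODY_RAMP_3PRIME = "body_ramp_3prime"
    BODY_UNIFORM = "body_uniform"
    BIMODAL_TSS_TES = "bimodal_tss_tes"


@dataclass
class MarkSpec:
    """Template shape and amplitude model for one mark."""

    name: str
    template_shape: TemplateShape = TemplateShape.BODY_UNIFORM
    shape_params: dict = field(default_factory=dict)
    amplitude_model: dict = field(
        default_factory=lambda: {
            "baseline": 1.0,
            "loading_on_activity": 0.0,
            "lognormal_sd": 0.3,
        }
    )
    # 'lognormal': A = baseline*exp(lam*z + sd*eta); 'affine': A = baseline + lam*z + sd*eta
    amplitude_family: str = "lognormal"

    def __post_init__(self) -> None:
        self.template_shape = TemplateShape(self.template_shape)
        if self.amplitude_model.get("baseline", 1.0) <= 0:
            raise ValueError("amplitude baseline must be positive")


@dataclass(frozen=True)
class PlantedTerm:
    """One term of the planted expression model.

    Contribution per gene is ``coef * prod_m f(A_m)`` over the marks in
    ``marks`` where ``f`` is the identity, or a hinge ``max(0, d*(A-knot))``
    when ``knot`` is set (``direction`` +1 or -1).
    """

    marks: tuple[int, ...]
    coef: float
    knot: float | None = None
    direction: int = 1

    def contribution(self, amplitudes: np.ndarray) -> np.ndarray:
        cols = amplitudes[:, list(self.marks)]
        if self.knot is not None:
            cols = np.maximum(0.0, self.direction * (cols - self.knot))
        return self.coef * cols.prod(axis=1)


@dataclass
class GroundTruth:
    activity: np.ndarray
    true_amplitudes: pd.DataFrame
    planted_terms: list[PlantedTerm]
    intercept: float
    expression_noise_sd: float
    expression: pd.Series


@dataclass
class SyntheticDataset:
    gene_models: list[GeneModel]
    mark_specs: list[MarkSpec]
    profiles: np.ndarray  # genes x marks x bins; None when not simulated
    expression_table: pd.DataFrame  # probe_id, gene_id, log2_expression
    ground_truth: GroundTruth
    rng_seed: int
    n_body_bins: int = 0
    flank_bins: int = 0

    @property
    def mark_names(self) -> list[str]:
        return [m.name for m in self.mark_specs]


def make_gene_models(
    n_genes: int,
    length_distribution: dict | None = None,
    alt_site_rate: float = 0.0,
    seed: int = 0,
    gap_bp: int = 6000,
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes on one synthetic chromosome.

    Lengths are log-normal (``log_mean``/``log_sd`` on the natural-log
    scale) floored at ``min_bp``; strand is Bernoulli(0.5); with probability
    ``alt_site_rate`` a gene gains one alternative start site, and
    independently with the same probability an alternative stop site.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    ld = {"log_mean": math.log(8138.0), "log_sd": 0.8, "min_bp": 200}
    if length_distribution:
        ld.update(length_distribution)
    if ld["min_bp"] < 1:
        raise ValueError("min_bp must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        rng.lognormal(ld["log_mean"], ld["log_sd"], size=n_genes).astype(int),
        ld["min_bp"],
    )
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = []
    cursor = gap_bp
    for i in range(n_genes):
        lo = cursor
        hi = lo + int(lengths[i])
        strand = str(strands[i])
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        starts, stops = [tss], [tes]
        if rng.random() < alt_site_rate:
            # alternative start inside the 5' half of the body
            off = int(rng.integers(1, max(2, lengths[i] // 2)))
            starts.append(tss + off if strand == "+" else tss - off)
        if rng.random() < alt_site_rate:
            off = int(rng.integers(1, max(2, lengths[i] // 2)))
            stops.append(tes - off if strand == "+" else tes + off)
        genes.append(
            GeneModel(
                gene_id=f"g{i:05d}",
                chrom="chr1",
                strand=strand,
                start_sites=starts,
                stop_sites=stops,
                chosen_tss=tss,
                chosen_tes=tes,
            )
        )
        cursor = hi + gap_bp
    return genes


def make_true_template(
    spec: MarkSpec, n_body_bins: int, flank_bins: int = 0
) -> np.ndarray:
    """Generate the mark's spatial template; strictly positive, mean exactly 1."""
    if n_body_bins < 2:
        raise ValueError("n_body_bins must be >= 2")
    if flank_bins < 0:
        raise ValueError("flank_bins must be >= 0")
    total = n_body_bins + 2 * flank_bins
    pos = np.arange(total, dtype=float)
    baseline = float(spec.shape_params.get("baseline", 0.2))
    shape = spec.template_shape
    if shape is TemplateShape.BODY_UNIFORM:
        values = np.ones(total)
    elif shape is TemplateShape.TSS_PEAK:
        width = float(spec.shape_params.get("peak_width", max(2.0, 0.05 * total)))
        center = float(flank_bins)
        values = baseline + np.exp(-0.5 * ((pos - center) / width) ** 2)
    elif shape is TemplateShape.BODY_RAMP_3PRIME:
        slope = float(spec.shape_params.get("ramp_slope", 2.0))
        values = np.full(total, baseline)
        body = np.arange(n_body_bins, dtype=float)
        values[flank_bins : flank_bins + n_body_bins] += (
            slope * (body + 1) / n_body_bins
        )
    elif shape is TemplateShape.BIMODAL_TSS_TES:
        width = float(spec.shape_params.get("peak_width", max(2.0, 0.05 * total)))
        c1, c2 = float(flank_bins), float(flank_bins + n_body_bins - 1)
        values = (
            baseline
            + np.exp(-0.5 * ((pos - c1) / width) ** 2)
            + np.exp(-0.5 * ((pos - c2) / width) ** 2)
        )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown template shape {shape!r}")
    values = values / values.mean()
    if np.any(values <= 0):
        raise ValueError("template must be strictly positive")
    return values


def simulate_amplitudes(
    mark_specs: list[MarkSpec], activity: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Draw per-gene positive amplitudes for each mark given latent activity."""
    rng = np.random.default_rng(seed)
    z = np.asarray(activity, float)
    n = z.shape[0]
    out = {}
    for spec in mark_specs:
        am = spec.amplitude_model
        base = float(am.get("baseline", 1.0))
        lam = float(am.get("loading_on_activity", 0.0))
        sd = float(am.get("lognormal_sd", 0.3))
        eta = rng.standard_normal(n)
        if spec.amplitude_family == "lognormal":
            a = base * np.exp(lam * z + sd * eta)
        elif spec.amplitude_family == "affine":
            a = np.maximum(base + lam * z + sd * eta, _POSITIVE_FLOOR)
        else:
            raise ValueError(f"unknown amplitude family {spec.amplitude_family!r}")
        out[spec.name] = a
    return pd.DataFrame(out, index=[f"g{i:05d}" for i in range(n)])


def simulate_profiles(
    gene_models: list[GeneModel],
    mark_specs: list[MarkSpec],
    true_amplitudes: pd.DataFrame | np.ndarray,
    n_body_bins: int,
    flank_bins: int = 0,
    noise: str = "poisson",
    seed: int = 0,
) -> np.ndarray:
    """Simulate per-gene per-mark binned profiles around amplitude x template.

    With ``noise='none'`` each profile is exactly ``A * template``; with
    ``noise='poisson'`` bin counts are Poisson with that mean.
    """
    A = np.asarray(true_amplitudes, float)
    n_genes, n_marks = A.shape
    if len(gene_models) != n_genes or len(mark_specs) != n_marks:
        raise ValueError("dimension mismatch between genes, marks and amplitudes")
    if np.any(A <= 0):
        raise ValueError("true amplitudes must be positive")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    total = n_body_bins + 2 * flank_bins
    profiles = np.empty((n_genes, n_marks, total))
    for j, spec in enumerate(mark_specs):
        t = make_true_template(spec, n_body_bins, flank_bins)
        mean = A[:, j][:, None] * t[None, :]
        if noise == "none":
            profiles[:, j, :] = mean
        else:
            profiles[:, j, :] = rng.poisson(mean)
    return profiles


def simulate_tags(
    gene_models: list[GeneModel],
    mark_specs: list[MarkSpec],
    true_amplitudes: pd.DataFrame | np.ndarray,
    flank_bp: int = 2000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """BED-emitting mode: per-base Poisson tag counts around A x template.

    Returns, per mark, a sorted array of genomic tag 5'-start positions on the
    genes' chromosome.  The per-base mean over a gene's window is the
    amplitude times a per-base-resolution template, so binned re-estimation
    recovers the amplitude in expectation.
    """
    A = np.asarray(true_amplitudes, float)
    rng = np.random.default_rng(seed)
    tags: dict[str, list[np.ndarray]] = {spec.name: [] for spec in mark_specs}
    for j, spec in enumerate(mark_specs):
        for k, gene in enumerate(gene_models):
            lo, hi = gene.body_interval()
            body_len = hi - lo
            t = make_true_template(spec, n_body_bins=body_len, flank_bins=flank_bp)
            if gene.strand == "-":
                t = t[::-1]
            counts = rng.poisson(A[k, j] * t)
            nz = np.nonzero(counts)[0]
            if nz.size:
                positions = np.repeat(nz + (lo - flank_bp), counts[nz])
                tags[spec.name].append(positions)
    return {
        name: (np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=int))
        for name, parts in tags.items()
    }


def rebinned_amplitude_sets(
    gene_models: list[GeneModel],
    mark_specs: list[MarkSpec],
    true_amplitudes: pd.DataFrame | np.ndarray,
    bin_counts: list[int],
    flank_bp: int = 2000,
    flank_bin_bp: int = 100,
    noise: str = "poisson",
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Amplitudes re-estimated from one per-base dataset at several bin counts.

    For each gene and mark a single per-base (1-bp resolution) profile is
    drawn around amplitude x template, then binned at every requested body
    bin count; templates are rebuilt from the binned data at each resolution
    before amplitudes are re-estimated.  This isolates the effect of bin-size
    choice on the amplitude estimates.
    """
    from .profiles import bin_counts as _bin, build_template, estimate_amplitudes

    A = np.asarray(true_amplitudes, float)
    n_genes, n_marks = A.shape
    rng = np.random.default_rng(seed)
    flank_bins = flank_bp // flank_bin_bp
    binned = {
        nb: np.empty((n_genes, n_marks, nb + 2 * flank_bins))
        for nb in bin_counts
    }
    for k, gene in enumerate(gene_models):
        lo, hi = gene.body_interval()
        body_len = hi - lo
        for j, spec in enumerate(mark_specs):
            t = make_true_template(spec, n_body_bins=body_len,
                                   flank_bins=flank_bp)
            mean = A[k, j] * t
            per_base = rng.poisson(mean).astype(float) if noise == "poisson" else mean
            left = per_base[:flank_bp].reshape(flank_bins, flank_bin_bp).mean(axis=1)
            body = per_base[flank_bp : flank_bp + body_len]
            right = per_base[flank_bp + body_len :].reshape(
                flank_bins, flank_bin_bp).mean(axis=1)
            for nb in bin_counts:
                binned[nb][k, j, :] = np.concatenate(
                    [left, _bin(body, nb), right])
    gene_ids = (list(true_amplitudes.index)
                if isinstance(true_amplitudes, pd.DataFrame)
                else [f"g{i:05d}" for i in range(n_genes)])
    mark_names = [s.name for s in mark_specs]
    out = {}
    for nb, arr in binned.items():
        est = np.empty((n_genes, n_marks))
        for j in range(n_marks):
            template = build_template(arr[:, j, :].mean(axis=0)[None, :])
            est[:, j] = estimate_amplitudes(arr[:, j, :], template.values)
        out[nb] = pd.DataFrame(est, index=gene_ids, columns=mark_names)
    return out


def simulate_expression(
    true_amplitudes: pd.DataFrame | np.ndarray,
    planted_terms: list[PlantedTerm],
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Planted log2 expression: intercept + sum of term contributions + noise."""
    A = np.asarray(true_amplitudes, float)
    n_genes, n_marks = A.shape
    for term in planted_terms:
        if any(m < 0 or m >= n_marks for m in term.marks):
            raise IndexError(f"planted term {term.marks} outside mark panel")
    y = np.full(n_genes, float(intercept))
    for term in planted_terms:
        y += term.contribution(A)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_genes)
    index = (
        true_amplitudes.index
        if isinstance(true_amplitudes, pd.DataFrame)
        else pd.RangeIndex(n_genes)
    )
    return pd.Series(y, index=index, name="log2_expression")


def confounded_loading(
    driver_cov: float, planted_coef: float, noise_sd: float
) -> float:
    """Activity loading that cancels Cov(R, Y) analytically.

    With R = a*z + noise_sd*v and Y = (other terms) + planted_coef*R + eps,
    Cov(R, Y) = a*driver_cov + planted_coef*(a^2 + noise_sd^2) where
    ``driver_cov`` = Cov(z, other terms).  Solves for the smaller positive
    root of the quadratic in ``a``.
    """
    if planted_coef >= 0:
        raise ValueError("planted_coef must be negative for a repressor")
    c = abs(planted_coef)
    ratio = driver_cov / c
    disc = ratio * ratio - 4.0 * noise_sd * noise_sd
    if disc < 0:
        raise ValueError(
            "no real cancelling loading: need driver_cov >= 2*|coef|*noise_sd"
        )
    return 0.5 * (ratio - math.sqrt(disc))


def make_confounded_repressor(
    activity: np.ndarray,
    cancel_marginal: bool = True,
    seed: int = 0,
    planted_coef: float = -0.8,
    driver_cov: float = 1.554,
    noise_sd: float = 0.5,
    baseline: float = 1.5,
) -> np.ndarray:
    """Amplitudes for a mark whose marginal link to expression cancels.

    When ``cancel_marginal`` the loading on activity is chosen so that the
    population covariance between this mark and the planted expression is
    exactly zero even though its planted coefficient is ``planted_coef`` < 0.
    Values are shifted by ``baseline`` and floored to stay positive.
    """
    z = np.asarray(activity, float)
    if not np.all(np.isfinite(z)):
        raise ValueError("activity must be finite")
    a = confounded_loading(driver_cov, planted_coef, noise_sd) if cancel_marginal else 0.0
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(z.shape[0])
    return np.maximum(baseline + a * z + noise_sd * v, _POSITIVE_FLOOR)


# ---------------------------------------------------------------------------
# Canned scenarios


_DEFAULT_SHAPES = [
    TemplateShape.TSS_PEAK,
    TemplateShape.BODY_RAMP_3PRIME,
    TemplateShape.BODY_UNIFORM,
    TemplateShape.BIMODAL_TSS_TES,
]


def _panel_specs(names: list[str], loadings: list[float], family: str,
                 baseline: float = 1.2, sd: float = 0.25) -> list[MarkSpec]:
    specs = []
    for i, (name, lam) in enumerate(zip(names, loadings)):
        specs.append(
            MarkSpec(
                name=name,
                template_shape=_DEFAULT_SHAPES[i % len(_DEFAULT_SHAPES)],
                shape_params={"peak_width": 8.0, "ramp_slope": 2.0, "baseline": 0.3},
                amplitude_model={
                    "baseline": baseline,
                    "loading_on_activity": lam,
                    "lognormal_sd": sd,
                },
                amplitude_family=family,
            )
        )
    return specs


def default_scenario(
    n_genes: int = 2000,
    seed: int = 0,
    n_body_bins: int = 200,
    flank_bins: int = 50,
    profile_noise: str = "none",
    noise_sd: float = 0.9,
    simulate_profile_data: bool = True,
) -> SyntheticDataset:
    """The 8-mark default panel: 4 activating, 3 repressive, 1 confounded.

    Amplitudes are affine in a shared latent activity (so the marginal
    cancellation of the confounded mark is exact); expression is linear in
    the planted terms, which include one bivalent activating product.
    """
    names = ["act1", "act2", "act3", "act4", "rep1", "rep2", "rep3", "conf"]
    loadings = [0.35, 0.35, 0.35, 0.35, -0.35, -0.35, -0.35, 0.0]
    specs = _panel_specs(names, loadings, family="affine")

    ss = np.random.SeedSequence(seed)
    s_gene, s_act, s_amp, s_conf, s_prof, s_expr = [
        int(c.generate_state(1)[0]) for c in ss.spawn(6)
    ]
    genes = make_gene_models(n_genes, alt_site_rate=0.0, seed=s_gene)
    rng = np.random.default_rng(s_act)
    z = rng.standard_normal(n_genes)
    amplitudes = simulate_amplitudes(specs, z, seed=s_amp)

    coef_conf = -0.8
    terms = [
        PlantedTerm((0,), 1.0),
        PlantedTerm((1,), 0.8),
        PlantedTerm((2, 3), 0.6),
        PlantedTerm((4,), -0.5),
        PlantedTerm((5,), -0.4),
        PlantedTerm((6,), -0.3),
        PlantedTerm((7,), coef_conf),
    ]
    # Cov(z, sum of non-confounded planted terms), exact for affine amplitudes:
    # mono terms contribute coef*loading, the bivalent term coef*(m_j*lam_l + m_l*lam_j).
    base, lam = 1.2, 0.35
    driver_cov = (
        1.0 * lam + 0.8 * lam  # act1, act2
        + 0.6 * (base * lam + base * lam)  # act3*act4
        + (-0.5) * -lam + (-0.4) * -lam + (-0.3) * -lam  # rep1..rep3
    )
    conf = make_confounded_repressor(
        z, cancel_marginal=True, seed=s_conf,
        planted_coef=coef_conf, driver_cov=driver_cov,
    )
    amplitudes["conf"] = conf

    intercept = 4.0
    expression = simulate_expression(
        amplitudes, terms, intercept=intercept, noise_sd=noise_sd, seed=s_expr
    )
    profiles = (
        simulate_profiles(
            genes, specs, amplitudes, n_body_bins, flank_bins,
            noise=profile_noise, seed=s_prof,
        )
        if simulate_profile_data
        else np.empty((n_genes, len(specs), 0))
    )
    expr_table = pd.DataFrame(
        {
            "probe_id": [f"p_{g}" for g in amplitudes.index],
            "gene_id": list(amplitudes.index),
            "log2_expression": expression.to_numpy(),
        }
    )
    truth = GroundTruth(
        activity=z,
        true_amplitudes=amplitudes,
        planted_terms=terms,
        intercept=intercept,
        expression_noise_sd=noise_sd,
        expression=expression,
    )
    return SyntheticDataset(
        gene_models=genes,
        mark_specs=specs,
        profiles=profiles,
        expression_table=expr_table,
        ground_truth=truth,
        rng_seed=seed,
        n_body_bins=n_body_bins if simulate_profile_data else 0,
        flank_bins=flank_bins if simulate_profile_data else 0,
    )


def planted_three_term_scenario(
    n_genes: int = 2000,
    seed: int = 0,
    n_marks: int = 8,
    r_squared: float = 0.5,
) -> SyntheticDataset:
    """Independent lognormal amplitudes with one mono, one bi and one tri term.

    Planted coefficients are rescaled so every term contributes equal
    variance (the raw lognormal triple product would otherwise dominate and
    starve the lower-valency terms of signal); signs are +, +, -.  Noise is
    scaled so the realized signal-to-total variance ratio equals
    ``r_squared``.  Profile simulation is skipped (amplitudes are the input
    to the regression stages).
    """
    names = [f"m{i}" for i in range(n_marks)]
    specs = _panel_specs(names, [0.0] * n_marks, family="lognormal",
                         baseline=1.0, sd=0.5)
    ss = np.random.SeedSequence(seed)
    s_amp, s_expr = [int(c.generate_state(1)[0]) for c in ss.spawn(2)]
    z = np.zeros(n_genes)
    amplitudes = simulate_amplitudes(specs, z, seed=s_amp)
    A = amplitudes.to_numpy()
    terms = []
    for marks, sign in [((0,), 1.0), ((1, 2), 1.0), ((3, 4, 5), -1.0)]:
        unit = PlantedTerm(marks, 1.0).contribution(A)
        terms.append(PlantedTerm(marks, sign / float(np.std(unit))))
    signal = np.zeros(n_genes)
    for term in terms:
        signal += term.contribution(A)
    noise_sd = float(np.std(signal) * math.sqrt((1.0 - r_squared) / r_squared))
    expression = simulate_expression(amplitudes, terms, intercept=4.0,
                                     noise_sd=noise_sd, seed=s_expr)
    expr_table = pd.DataFrame(
        {
            "probe_id": [f"p_{g}" for g in amplitudes.index],
            "gene_id": list(amplitudes.index),
            "log2_expression": expression.to_numpy(),
        }
    )
    truth = GroundTruth(z, amplitudes, terms, 4.0, noise_sd, expression)
    return SyntheticDataset(
        gene_models=[],
        mark_specs=specs,
        profiles=np.empty((n_genes, n_marks, 0)),
        expression_table=expr_table,
        ground_truth=truth,
        rng_seed=seed,
    )


def hinge_scenario(
    n_genes: int = 1000,
    seed: int = 0,
    knot: float = 0.7,
    coef: float = 2.0,
    noise_sd: float = 0.0,
    n_marks: int = 3,
) -> SyntheticDataset:
    """Expression exactly representable by one hinge: coef * h(A_0 - knot).

    The requested knot is snapped to the nearest observed amplitude of mark 0
    so a knot search over data values can recover it exactly.
    """
    names = [f"m{i}" for i in range(n_marks)]
    specs = _panel_specs(names, [0.0] * n_marks, family="lognormal",
                         baseline=1.0, sd=0.5)
    ss = np.random.SeedSequence(seed)
    s_amp, s_expr = [int(c.generate_state(1)[0]) for c in ss.spawn(2)]
    amplitudes = simulate_amplitudes(specs, np.zeros(n_genes), seed=s_amp)
    observed = amplitudes.iloc[:, 0].to_numpy()
    knot = float(observed[np.argmin(np.abs(observed - knot))])
    terms = [PlantedTerm((0,), coef, knot=knot, direction=1)]
    expression = simulate_expression(amplitudes, terms, intercept=1.0,
                                     noise_sd=noise_sd, seed=s_expr)
    expr_table = pd.DataFrame(
        {
            "probe_id": [f"p_{g}" for g in amplitudes.index],
            "gene_id": list(amplitudes.index),
            "log2_expression": expression.to_numpy(),
        }
    )
    truth = GroundTruth(np.zeros(n_genes), amplitudes, terms, 1.0, noise_sd,
                        expression)
    return SyntheticDataset(
        gene_models=[],
        mark_specs=specs,
        profiles=np.empty((n_genes, n_marks, 0)),
        expression_table=expr_table,
        ground_truth=truth,
        rng_seed=seed,
    )
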