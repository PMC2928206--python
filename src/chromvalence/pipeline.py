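"""End-to-end orchestration: simulate -> amplitudes -> significance -> models
-> knockouts, with one master seed and a provenance manifest."""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .knockout import knockout, knockout_screen, quintile_stratify
from .mars import fit_mars, mars_report
from .multilinear import cv_protocol, enumerate_terms, round1_survival, \
    build_design, term_statistics
from .profiles import build_template, estimate_amplitudes, cv_rmsd
from .significance import call_significance
from .synthetic import default_scenario

__all__ = ["RunConfig", "run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # synthetic inputs (used when no file inputs are given)
    n_genes: int = 2000
    n_body_bins: int = 200
    flank_bins: int = 50
    profile_noise: str = "poisson"
    # file inputs (optional; override the synthetic stage)
    profiles_dir: str | None = None
    expression_path: str | None = None
    # significance
    fdr_cutoff: float = 0.05
    mode_estimator: str = "kde"
    # multilinear
    survival_runs: int = 30
    survival_cutoff: float = 0.35
    n_initial: int = 30
    n_folds: int = 10
    runs_per_fold: int = 5
    extra_random_terms: int = 20
    retention: int = 5
    # mars
    max_degree: int = 3
    mars_penalty: float = 3.0
    max_knots: int = 50
    max_terms: int = 41
    knockout_pairs: bool = True
    extras: dict = field(default_factory=dict)


def _child_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items() if k != "extras"},
        "stages": {},
        "warnings": [],
        "decisions": {
            "mode_estimator": config.mode_estimator,
            "enp_formula": "T + penalty * n_distinct_knots",
            "trim_rule": "drop single min and max across folds",
            "site_flags": "internal Gaussian-null significance calls",
        },
    }
    stage = "simulate"
    try:
        t0 = time.time()
        if config.profiles_dir and config.expression_path:
            profile_paths = sorted(Path(config.profiles_dir).glob("profiles_*.tsv"))
            if not profile_paths:
                raise FileNotFoundError(
                    f"no profiles_*.tsv under {config.profiles_dir}")
            mark_names = [p.stem.removeprefix("profiles_") for p in profile_paths]
            mats = [io.read_profile_matrix(p) for p in profile_paths]
            gene_ids = list(mats[0].index)
            profiles = np.stack([m.to_numpy() for m in mats], axis=1)
            expr_table = io.read_expression(config.expression_path)
            dataset = None
        else:
            dataset = default_scenario(
                n_genes=config.n_genes, seed=config.seed,
                n_body_bins=config.n_body_bins, flank_bins=config.flank_bins,
                profile_noise=config.profile_noise,
            )
            io.write_dataset(dataset, out / "synthetic")
            mark_names = dataset.mark_names
            gene_ids = list(dataset.ground_truth.true_amplitudes.index)
            profiles = dataset.profiles
            expr_table = dataset.expression_table
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "marks": mark_names,
                                     "n_genes": len(gene_ids)}
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    stage = "amplitudes"
    try:
        t0 = time.time()
        amps = {}
        cvs = {}
        for j, name in enumerate(mark_names):
            mat = profiles[:, j, :]
            template = build_template(mat.mean(axis=0)[None, :])
            a = estimate_amplitudes(mat, template.values)
            amps[name] = a
            cvs[name] = [cv_rmsd(mat[i], template.values, a[i]) if a[i] > 0
                         else np.nan for i in range(mat.shape[0])]
        amplitudes = pd.DataFrame(amps, index=gene_ids)
        cv_table = pd.DataFrame(cvs, index=gene_ids)
        io.write_amplitudes(amplitudes, out / "amplitudes.tsv")
        io.write_amplitudes(cv_table, out / "cv_rmsd.tsv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    stage = "significance"
    try:
        t0 = time.time()
        calls, nulls = call_significance(amplitudes, config.fdr_cutoff,
                                         config.mode_estimator)
        sig_long = pd.DataFrame({
            "gene_id": np.repeat(gene_ids, len(mark_names)),
            "mark": mark_names * len(gene_ids),
            "amplitude": amplitudes.to_numpy().ravel(),
            "p": calls.pvalues.to_numpy().ravel(),
            "q": calls.qvalues.to_numpy().ravel(),
            "significant": calls.significant.to_numpy().ravel(),
        })
        sig_long.to_csv(out / "significance.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "nulls": {k: {"mu": v.mu, "sigma": v.sigma} for k, v in nulls.items()},
        }
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    stage = "mlm"
    try:
        t0 = time.time()
        if expr_table is None or expr_table.empty:
            raise ValueError("no expression data")
        amp_by_probe = amplitudes.loc[expr_table["gene_id"]].to_numpy()
        y = expr_table["log2_expression"].to_numpy()
        genes_of_probe = expr_table["gene_id"].to_numpy()
        terms = enumerate_terms(len(mark_names))
        design = build_design(amp_by_probe, terms)
        _, surviving = round1_survival(
            design, y, terms, n_runs=config.survival_runs,
            cutoff=config.survival_cutoff, n_initial=config.n_initial,
            seed=_child_seed(config.seed, "round1"),
        )
        ml = cv_protocol(
            amp_by_probe, y, surviving, candidate_terms=terms,
            gene_ids=genes_of_probe, n_folds=config.n_folds,
            runs_per_fold=config.runs_per_fold,
            extra_random_terms=config.extra_random_terms,
            retention=config.retention,
            seed=_child_seed(config.seed, "cv"),
        )
        stats = term_statistics(ml, amp_by_probe, mark_names)
        stats.to_csv(out / "mlm_terms.tsv", sep="\t", index=False)
        _dump_json(out / "mlm_model.json", {
            "terms": [list(t) for t in ml.terms],
            "intercept": ml.intercept,
            "beta": ml.beta.tolist(),
            "train_mse": ml.train_mse.tolist(),
            "test_mse": ml.test_mse.tolist(),
            "train_adj_r2": ml.train_adj_r2.tolist(),
            "test_adj_r2": ml.test_adj_r2.tolist(),
            "metadata": ml.metadata,
        })
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_terms": len(ml.terms),
            "mean_train_mse": float(ml.train_mse.mean()),
            "mean_test_mse": float(ml.test_mse.mean()),
        }
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    stage = "mars"
    try:
        t0 = time.time()
        mars_model = fit_mars(
            amp_by_probe, y, max_degree=config.max_degree,
            max_terms=config.max_terms, max_knots=config.max_knots,
            penalty=config.mars_penalty,
        )
        basis_table, impact_table = mars_report(mars_model, amp_by_probe,
                                                mark_names)
        basis_table.to_csv(out / "mars_terms.tsv", sep="\t", index=False)
        impact_table.to_csv(out / "mars_impact.tsv", sep="\t", index=False)
        _dump_json(out / "mars_model.json", {
            "intercept": mars_model.intercept,
            "bases": [
                {"coefficient": float(c),
                 "factors": [{"mark": f.mark, "knot": f.knot,
                              "direction": f.direction} for f in b.factors]}
                for b, c in zip(mars_model.bases, mars_model.coefficients)
            ],
            "gcv": mars_model.gcv,
            "mse": mars_model.mse,
            "r2": mars_model.r2,
            "metadata": mars_model.metadata,
        })
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "n_bases": len(mars_model.bases),
                                     "mse": mars_model.mse,
                                     "r2": mars_model.r2}
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    stage = "knockout"
    try:
        t0 = time.time()
        for label, model in [("mlm", ml), ("mars", mars_model)]:
            screen = knockout_screen(model, amp_by_probe,
                                     pairs=config.knockout_pairs,
                                     mark_names=mark_names)
            screen.to_csv(out / f"knockout_{label}.tsv", sep="\t", index=False)
            worst = screen.iloc[0]
            if worst["n_marks"] == 1:
                res = knockout(model, amp_by_probe, worst["marks"])
                quintile_stratify(res).to_csv(
                    out / f"knockout_{label}_quintiles.tsv", sep="\t",
                    index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as exc:  # noqa: BLE001
        _persist(manifest, out)
        raise StageError(stage, exc) from exc

    _persist(manifest, out)
    return manifest


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _persist(manifest: dict, out: Path) -> None:
    _dump_json(out / "manifest.json", manifest)
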