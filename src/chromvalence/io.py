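"""Plain-text readers and writers for the pipeline's tables.

Genes travel as a BED12-like TSV with alternative start/stop columns, tags
as BED6, binned profiles as one TSV matrix per mark, expression as a
probe/gene/value TSV, and ground truth as a JSON sidecar.  All coordinates
are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import GeneModel
from .synthetic import GroundTruth, PlantedTerm, SyntheticDataset

__all__ = [
    "write_gene_table",
    "read_gene_table",
    "write_tags_bed",
    "read_tags_bed",
    "write_profile_matrix",
    "read_profile_matrix",
    "write_expression",
    "read_expression",
    "write_amplitudes",
    "read_amplitudes",
    "write_ground_truth",
    "read_ground_truth",
    "write_dataset",
]

_GENE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                 "alt_starts", "alt_ends"]


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        lo, hi = g.body_interval()
        rows.append({
            "chrom": g.chrom,
            "start": lo,
            "end": hi,
            "name": g.gene_id,
            "score": 0,
            "strand": g.strand,
            "alt_starts": ",".join(str(s) for s in g.start_sites),
            "alt_ends": ",".join(str(s) for s in g.stop_sites),
        })
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"alt_starts": str, "alt_ends": str})
    genes = []
    for _, row in df.iterrows():
        starts = [int(s) for s in str(row["alt_starts"]).split(",")]
        stops = [int(s) for s in str(row["alt_ends"]).split(",")]
        strand = str(row["strand"])
        tss = int(row["start"]) if strand == "+" else int(row["end"])
        tes = int(row["end"]) if strand == "+" else int(row["start"])
        genes.append(GeneModel(
            gene_id=str(row["name"]), chrom=str(row["chrom"]), strand=strand,
            start_sites=starts, stop_sites=stops,
            chosen_tss=tss, chosen_tes=tes,
        ))
    return genes


def write_tags_bed(positions: np.ndarray, path, chrom: str = "chr1") -> None:
    """Tag 5' start positions as 1-bp BED6 intervals."""
    positions = np.asarray(positions, dtype=int)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": positions,
        "end": positions + 1,
        "name": ".",
        "score": 0,
        "strand": "+",
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path) -> np.ndarray:
    """5' start positions from a BED file (strand-aware: minus tags use end-1)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 5] if _bed_has_strand(path) else [0, 1, 2])
    if df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "strand"]
        pos = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    else:
        df.columns = ["chrom", "start", "end"]
        pos = df["start"].to_numpy()
    return np.sort(np.asarray(pos, dtype=int))


def _bed_has_strand(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return len(first.rstrip("\n").split("\t")) >= 6


def write_profile_matrix(profiles: np.ndarray, gene_ids: list[str], path) -> None:
    """One mark's genes x bins profile matrix."""
    pd.DataFrame(np.asarray(profiles), index=gene_ids).to_csv(path, sep="\t")


def read_profile_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(table: pd.DataFrame, path) -> None:
    cols = ["probe_id", "gene_id", "log2_expression"]
    table[cols].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "log2_expression" not in df.columns:
        raise ValueError("expression table needs a log2_expression column")
    if "gene_id" not in df.columns:
        raise ValueError("expression table needs a gene_id column")
    if "probe_id" not in df.columns:
        df["probe_id"] = df["gene_id"]
    return df[["probe_id", "gene_id", "log2_expression"]]


def write_amplitudes(amplitudes: pd.DataFrame, path) -> None:
    amplitudes.to_csv(path, sep="\t", index_label="gene_id")


def read_amplitudes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "intercept": truth.intercept,
        "expression_noise_sd": truth.expression_noise_sd,
        "activity": [float(v) for v in truth.activity],
        "planted_terms": [
            {"marks": list(t.marks), "coef": t.coef, "knot": t.knot,
             "direction": t.direction}
            for t in truth.planted_terms
        ],
        "true_amplitudes": {
            "index": list(truth.true_amplitudes.index),
            "columns": list(truth.true_amplitudes.columns),
            "values": truth.true_amplitudes.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    amp = pd.DataFrame(
        payload["true_amplitudes"]["values"],
        index=payload["true_amplitudes"]["index"],
        columns=payload["true_amplitudes"]["columns"],
    )
    terms = [
        PlantedTerm(tuple(t["marks"]), t["coef"], t["knot"], t["direction"])
        for t in payload["planted_terms"]
    ]
    return GroundTruth(
        activity=np.asarray(payload["activity"], dtype=float),
        true_amplitudes=amp,
        planted_terms=terms,
        intercept=payload["intercept"],
        expression_noise_sd=payload["expression_noise_sd"],
        expression=pd.Series(dtype=float),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write a synthetic dataset's tables under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if dataset.gene_models:
        paths["genes"] = str(out / "genes.tsv")
        write_gene_table(dataset.gene_models, paths["genes"])
    gene_ids = list(dataset.ground_truth.true_amplitudes.index)
    if dataset.profiles.size:
        for j, name in enumerate(dataset.mark_names):
            p = out / f"profiles_{name}.tsv"
            write_profile_matrix(dataset.profiles[:, j, :], gene_ids, p)
            paths[f"profiles_{name}"] = str(p)
    paths["expression"] = str(out / "expression.tsv")
    write_expression(dataset.expression_table, paths["expression"])
    paths["ground_truth"] = str(out / "ground_truth.json")
    write_ground_truth(dataset.ground_truth, paths["ground_truth"])
    paths["true_amplitudes"] = str(out / "true_amplitudes.tsv")
    write_amplitudes(dataset.ground_truth.true_amplitudes,
                     paths["true_amplitudes"])
    return paths
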