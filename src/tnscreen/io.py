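"""Readers and writers for the pipeline's TSV schemas.

Long-format TSV is the canonical interchange for site counts; all writers
produce deterministic column order and gene_id-sorted rows, and every run
directory gets a params.json capturing the parameters and input hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError

SITE_COUNT_COLUMNS = ["gene_id", "position_bp", "count", "sample_id"]
MANIFEST_COLUMNS = ["sample_id", "timepoint_days", "replicate"]
GENE_COLUMNS = ["gene_id", "length_bp"]


def _read_tsv(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} {path}: missing columns {missing}")
    return df


def read_site_counts(path) -> pd.DataFrame:
    """Long-format site counts: gene_id, position_bp, count, sample_id.

    Errors name offending line numbers (1-based, counting the header).
    """
    df = _read_tsv(path, SITE_COUNT_COLUMNS, "site-count table")
    lines = df.index + 2  # header is line 1
    neg = df["count"] < 0
    if neg.any():
        raise ValidationError(
            f"{path}: negative counts at lines {list(lines[neg])[:10]}"
        )
    bad_pos = df["position_bp"] < 1
    if bad_pos.any():
        raise ValidationError(
            f"{path}: positions < 1 at lines {list(lines[bad_pos])[:10]}"
        )
    dup = df.duplicated(subset=["gene_id", "position_bp", "sample_id"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["gene_id", "position_bp", "sample_id"]]
        raise ValidationError(
            f"{path}: duplicate (gene, position, sample) rows at lines "
            f"{list(lines[dup])[:10]}:\n{offenders.head(10)}"
        )
    return df


def read_manifest(path) -> pd.DataFrame:
    df = _read_tsv(path, MANIFEST_COLUMNS, "sample manifest")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id rows")
    if df.duplicated(subset=["timepoint_days", "replicate"]).any():
        raise ValidationError(f"{path}: duplicate (timepoint, replicate) pairs")
    return df


def read_gene_table(path) -> pd.DataFrame:
    df = _read_tsv(path, GENE_COLUMNS, "gene annotation table")
    if df["gene_id"].duplicated().any():
        dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValidationError(f"{path}: duplicate gene_ids {dups[:10]}")
    if (df["length_bp"] < 1).any():
        raise ValidationError(f"{path}: non-positive gene lengths")
    return df


def read_exclusion_list(path) -> list[str]:
    """Plain-text gene list, one id per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    return genes


def read_expression_table(path) -> pd.DataFrame:
    """Genes x samples expression/count matrix with a gene_id column."""
    df = _read_tsv(path, ["gene_id"], "expression table")
    return df.set_index("gene_id")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_params_json(
    out_dir, config: PipelineConfig | dict, inputs: dict[str, str],
    extra: dict | None = None,
) -> Path:
    """Record run parameters and SHA-256 of every input file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.to_dict() if isinstance(config, PipelineConfig) else dict(config)
    payload = {
        "params": params,
        "input_sha256": {name: _hash_file(p) for name, p in inputs.items()},
    }
    if extra:
        payload.update(extra)
    path = out_dir / "params.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_fitness_results(results, out_dir) -> dict[str, Path]:
    """Write the standard output set for one screen run.

    Per-sample RpK tables, per-timepoint call tables, the longevity-set
    table and a fit report; deterministic ordering throughout.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for sample_id in sorted(results.sample_tables):
        table = results.sample_tables[sample_id].sort_values("gene_id")
        p = out_dir / f"rpk_{sample_id}.tsv"
        table.to_csv(p, sep="\t", index=False)
        written[f"rpk_{sample_id}"] = p

    for tp in sorted(results.timepoint_calls):
        table = results.timepoint_calls[tp].sort_values("gene_id")
        p = out_dir / f"calls_t{tp:g}d.tsv"
        table.to_csv(p, sep="\t", index=False)
        written[f"calls_t{tp:g}d"] = p

    longevity = results.longevity.sort_values("gene_id")
    p = out_dir / "longevity_set.tsv"
    longevity.to_csv(p, sep="\t", index=False)
    written["longevity_set"] = p

    # plain gene list, directly consumable by `enrich --set`
    p = out_dir / "longevity_genes.txt"
    p.write_text("".join(f"{g}\n" for g in results.longevity_genes))
    written["longevity_genes"] = p

    fit_rows = [
        {
            "sample_id": s,
            "mu": f.mu,
            "sigma": f.sigma,
            "amplitude": f.amplitude,
            "rmse": f.rmse,
            "n_bins": f.n_bins,
            "bin_width": f.bin_width,
        }
        for s, f in sorted(results.fits.items())
    ]
    p = out_dir / "fit_report.tsv"
    pd.DataFrame(fit_rows).to_csv(p, sep="\t", index=False)
    written["fit_report"] = p
    return written
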