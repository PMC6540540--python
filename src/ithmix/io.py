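"""Reading mutation/segment tables and serializing inference results.

The native mutation format is a headered TSV with one row per somatic point
mutation: ``chrom, pos, ref, alt, alt_count, ref_count, cn_minor, cn_major``
(1-based inclusive coordinates; chromosome names accepted with or without a
"chr" prefix).  A VCF dialect is also accepted: allele depths are taken from
the first sample's ``AD`` field and allele-specific copy numbers are attached
from a companion segment TSV by position overlap.  Results are written as a
full JSON document (every retained configuration fit) plus a one-row TSV
summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .likelihood import FitResult, ModelParams
from .selection import IthSummary
from .trees import CopyState, TreeConfig

__all__ = [
    "read_mutations",
    "read_segments",
    "write_results",
    "read_results",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

MUTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_count",
    "ref_count",
    "cn_minor",
    "cn_major",
]


def read_segments(path: str | Path) -> pd.DataFrame:
    """Segment TSV: chrom, start, end (1-based inclusive), cn_minor, cn_major."""
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "cn_minor", "cn_major"}
    missing = required - set(seg.columns)
    if missing:
        raise ValueError(f"segment table is missing columns: {sorted(missing)}")
    seg["chrom"] = seg["chrom"].str.replace("^chr", "", regex=True)
    return seg


def _lookup_state(seg: pd.DataFrame, chrom: str, pos: int) -> tuple[int, int] | None:
    hit = seg[(seg["chrom"] == chrom) & (seg["start"] <= pos) & (pos <= seg["end"])]
    if len(hit) == 0:
        return None
    row = hit.iloc[0]
    return int(row["cn_minor"]), int(row["cn_major"])


def _read_vcf(path: str | Path, segments: pd.DataFrame, report: dict) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                report["skipped_rows"] += 1
                continue
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                report["skipped_rows"] += 1
                continue
            chrom = str(rec.chrom).removeprefix("chr")
            state = _lookup_state(segments, chrom, rec.pos)
            if state is None:
                report["no_segment"] += 1
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "alt_count": int(ad[1]),
                    "ref_count": int(ad[0]),
                    "cn_minor": state[0],
                    "cn_major": state[1],
                }
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_mutations(
    path: str | Path,
    segments: str | Path | pd.DataFrame | None = None,
    report: dict | None = None,
) -> pd.DataFrame:
    """Read a mutation table (TSV, or VCF with a companion segment table).

    Rows failing basic validity (negative counts, alt deeper than total,
    unparseable numbers) are skipped and tallied in ``report``; missing
    required columns abort.
    """
    report = report if report is not None else {}
    report.setdefault("skipped_rows", 0)
    report.setdefault("no_segment", 0)
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        if segments is None:
            raise ValueError("VCF input requires a segment table for copy numbers")
        seg = segments if isinstance(segments, pd.DataFrame) else read_segments(segments)
        table = _read_vcf(path, seg, report)
    else:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(MUTATION_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"mutation table is missing columns: {sorted(missing)}")
        table = table[MUTATION_COLUMNS].copy()
        table["chrom"] = table["chrom"].str.replace("^chr", "", regex=True)
    numeric = ["pos", "alt_count", "ref_count", "cn_minor", "cn_major"]
    for col in numeric:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    ok = (
        table[numeric].notna().all(axis=1)
        & (table["alt_count"] >= 0)
        & (table["ref_count"] >= 0)
        & (table["alt_count"] + table["ref_count"] >= 1)
        & (table["cn_minor"] >= 0)
        & (table["cn_major"] >= table["cn_minor"])
    )
    report["skipped_rows"] += int((~ok).sum())
    table = table.loc[ok].reset_index(drop=True)
    table[numeric] = table[numeric].astype(int)
    return table


# ---------------------------------------------------------------------------
# Results serialization
# ---------------------------------------------------------------------------


def _state_key(state: CopyState) -> str:
    return f"{state.cn_minor},{state.cn_major}"


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "config": fit.config.to_dict(),
        "loglik": fit.loglik,
        "model_size": fit.model_size,
        "bic": fit.bic,
        "entropy": fit.entropy,
        "posterior_weight": fit.posterior_weight,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "epsilon": fit.params.epsilon,
        "theta": fit.params.theta.tolist(),
        "pi": {_state_key(s): p.tolist() for s, p in fit.params.pi.items()},
        "map_combo": fit.map_combo.tolist(),
        "map_origin": fit.map_origin.tolist(),
        "map_prevalence": fit.map_prevalence.tolist(),
    }


def _fit_from_dict(d: dict) -> FitResult:
    cfg = d["config"]
    tree = TreeConfig(
        index=cfg["index"],
        n_subclones=cfg["n_subclones"],
        parent=tuple(None if p == -1 else p for p in cfg["parent"]),
        allocations=tuple(tuple(a) for a in cfg["allocations"]),
    )
    pi = {
        CopyState(*(int(x) for x in key.split(","))): np.array(val)
        for key, val in d["pi"].items()
    }
    return FitResult(
        config=tree,
        loglik=d["loglik"],
        model_size=d["model_size"],
        bic=d["bic"],
        entropy=d["entropy"],
        params=ModelParams(epsilon=d["epsilon"], theta=np.array(d["theta"]), pi=pi),
        map_combo=np.array(d["map_combo"], dtype=int),
        map_origin=np.array(d["map_origin"], dtype=int),
        map_prevalence=np.array(d["map_prevalence"]),
        converged=d["converged"],
        n_iter=d["n_iter"],
        posterior_weight=d["posterior_weight"],
    )


def write_results(
    summary: IthSummary,
    sample_id: str,
    purity: float,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the full JSON results and the one-row TSV summary for a sample."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "sample_id": sample_id,
        "purity": purity,
        "n_spms": int(len(summary.prevalence)),
        "summary": summary.to_row(),
        "prevalence": summary.prevalence.tolist(),
        "fits": [_fit_to_dict(f) for f in summary.fits],
    }
    json_path = out_dir / f"{sample_id}.results.json"
    json_path.write_text(json.dumps(doc, indent=1))
    row = {
        "sample_id": sample_id,
        "S_opt": summary.n_subclones,
        "E_o": summary.entropy_optimal,
        "E_w": summary.entropy_weighted,
        "H": summary.high_ith,
        "purity": purity,
        "n_spms": int(len(summary.prevalence)),
    }
    tsv_path = out_dir / f"{sample_id}.summary.tsv"
    pd.DataFrame([row]).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def read_results(json_path: str | Path) -> dict:
    """Load a results JSON back into fit objects and the summary fields."""
    doc = json.loads(Path(json_path).read_text())
    doc["fits"] = [_fit_from_dict(d) for d in doc["fits"]]
    doc["prevalence"] = np.array(doc["prevalence"])
    return doc
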