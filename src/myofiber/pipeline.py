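"""End-to-end pipeline runners and report writing.

Each runner validates and computes everything in memory first and only then
writes its output files, so a failing run leaves no partial outputs.  Every
run writes a ``manifest.json`` recording all parameters, the seed, and the
package version - enough to reproduce the run exactly.  Report tables are
written twice: the primary TSV rendered at 6 significant digits for
diff-ability, and a ``*.full.tsv`` companion at full precision.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, proteome, relax, simulate
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

REPORT_DIGITS = 6


def _render(df: pd.DataFrame, digits: int = REPORT_DIGITS) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{digits}g}"
            )
    return out


def write_report_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    """Write a TSV at 6 significant digits plus a full-precision companion."""
    path = Path(path)
    _render(df).to_csv(path, sep="\t", index=index)
    full = path.with_name(path.stem + ".full.tsv")
    df.to_csv(full, sep="\t", index=index)


def _write_manifest(out_dir: Path, params: dict, outputs: list[str]) -> None:
    try:
        pkg_version = _pkg_version("myofiber")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package": "myofiber",
        "version": pkg_version,
        "parameters": params,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_relax_pipeline(
    traces_path: str,
    out_dir: str,
    baseline_label: str | None = None,
    stratum_col: str | None = "group",
    myosin_conc: float = relax.MYOSIN_CONC_UM,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit a trace file end to end: preprocess, fit, score, compare.

    Writes ``fits.tsv`` (per-fiber parameters and ATP scores in both formula
    variants), ``subject_means.tsv``, ``comparisons.tsv`` (fiber- and
    subject-level tests), optionally ``relative_change.tsv`` when a baseline
    treatment label is given, and ``manifest.json``.
    """
    if not Path(traces_path).exists():
        raise InvalidInputError(f"trace file not found: {traces_path}")
    traces = relax.read_traces(traces_path)
    fits = relax.fit_traces(traces, myosin_conc=myosin_conc)

    results: dict[str, pd.DataFrame] = {"fits": fits}
    converged = fits[fits["converged"]]
    if converged["subject_id"].astype(bool).any():
        results["subject_means"] = groupstats.aggregate_by_subject(
            converged,
            value_cols=["p1", "p2", "t1", "t2", "atp_corrected", "atp_verbatim"],
        )
    if converged["group"].astype(bool).any() and converged["group"].nunique() > 1:
        results["comparisons"] = groupstats.comparisons_table(converged)
    if baseline_label is not None:
        results["relative_change"] = relax.relative_change(
            converged, baseline_label=baseline_label, stratum_col=stratum_col
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        write_report_table(df, out / f"{name}.tsv")
    _write_manifest(
        out,
        {
            "traces_path": str(traces_path),
            "baseline_label": baseline_label,
            "stratum_col": stratum_col,
            "myosin_conc": myosin_conc,
            "seed": seed,
        },
        [f"{n}.tsv" for n in results],
    )
    return results


def run_proteome_pipeline(
    matrix_path: str,
    groups_path: str,
    out_dir: str,
    case: str,
    control: str,
    treated_case: str | None = None,
    annotation_path: str | None = None,
    scale: str = "log2",
    normalize: bool = False,
    max_missing_frac: float = 0.5,
    knn_valid_frac: float = 0.6,
    k: int = 3,
    width: float = 0.3,
    shift: float = 1.8,
    alpha: float = 0.05,
    fc: float = 2.0,
    use_adjusted: bool = True,
    direction: str = "both",
    min_targets: int = 5,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the proteomics arm end to end on a matrix + group map.

    Stages: (optional) total-abundance normalization and log2 transform for
    raw input, missingness filter, mixed KNN/MinProb imputation, differential
    abundance for case-vs-control (and treated-case-vs-control when given),
    restoration sets across the two contrasts, hypergeometric enrichment of
    the hits against an annotation, and PCA scores.  Writes one TSV per
    stage plus ``manifest.json``.
    """
    for path in (matrix_path, groups_path):
        if not Path(path).exists():
            raise InvalidInputError(f"input file not found: {path}")
    if annotation_path is not None and not Path(annotation_path).exists():
        raise InvalidInputError(f"annotation file not found: {annotation_path}")
    m = proteome.AbundanceMatrix.from_files(matrix_path, groups_path, scale=scale)
    if m.scale == "raw":
        if normalize:
            m = proteome.normalize_total_abundance(m)
        m = proteome.log2_transform(m)
    m, dropped = proteome.filter_by_missingness(m, max_missing_frac)
    m, report = proteome.mixed_impute(
        m, knn_valid_frac=knn_valid_frac, k=k, width=width, shift=shift, seed=seed
    )
    diff = proteome.differential_abundance(
        m, case, control, alpha=alpha, fc=fc, use_adjusted=use_adjusted
    )
    results: dict[str, pd.DataFrame] = {
        "differential": diff.reset_index(names="protein_id")
    }
    hits = set(diff.index[diff["significant"]])
    if treated_case is not None:
        diff_treated = proteome.differential_abundance(
            m, treated_case, control, alpha=alpha, fc=fc, use_adjusted=use_adjusted
        )
        results["differential_treated"] = diff_treated.reset_index(
            names="protein_id"
        )
        sets = proteome.restoration_sets(diff, diff_treated, direction=direction)
        rows = [
            {"protein_id": p, "category": cat}
            for cat in ("maintained", "restored", "emergent", "discordant")
            for p in sorted(getattr(sets, cat))
        ]
        results["restoration"] = pd.DataFrame(
            rows, columns=["protein_id", "category"]
        )
    if annotation_path is not None:
        annotation = simulate.read_annotation(annotation_path)
        results["enrichment"] = proteome.hypergeometric_enrichment(
            hits, annotation, set(m.protein_ids), min_targets=min_targets
        )
    scores, evr = proteome.pca_scores(m)
    results["pca"] = scores.reset_index(names="sample_id")
    results["pca_variance"] = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(evr))],
            "explained_variance_fraction": evr,
        }
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        write_report_table(df, out / f"{name}.tsv")
    _write_manifest(
        out,
        {
            "matrix_path": str(matrix_path),
            "groups_path": str(groups_path),
            "annotation_path": annotation_path,
            "case": case,
            "control": control,
            "treated_case": treated_case,
            "scale": scale,
            "normalize": normalize,
            "max_missing_frac": max_missing_frac,
            "knn_valid_frac": knn_valid_frac,
            "k": k,
            "width": width,
            "shift": shift,
            "alpha": alpha,
            "fc": fc,
            "use_adjusted": use_adjusted,
            "direction": direction,
            "min_targets": min_targets,
            "seed": seed,
            "n_dropped_by_filter": len(dropped),
        },
        [f"{n}.tsv" for n in results],
    )
    return results
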