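"""End-to-end seeded analysis pipeline and table renderers.

``run_pipeline`` drives the full analysis chain on a cohort — relative
risks by zygosity, polychoric correlations with the multiple-threshold
goodness-of-fit test, and the nested variance-component model ladder —
and lays the results out as four delimited tables (familial relative
risks; liability-model fit p-values; polychoric correlations; model-fit
statistics with variance estimates), each with a machine-readable JSON
twin, plus a run manifest.  Reruns with the same configuration and seed
are bit-identical.  Logging goes to stderr and never interleaves with
results.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .familial_clustering import crosstab, relative_risk, symmetrize
from .io import read_twin_table, write_twin_table
from .liability_correlation import fit_polychoric
from .synthetic_cohort import TwinPairRecord, preset_params, simulate_cohort
from .variance_components import (
    MODEL_LADDER,
    ModelSpec,
    fit_model,
    likelihood_ratio_test,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "render_rr_table",
    "render_gof_table",
    "render_polychoric_table",
    "render_model_table",
]

log = logging.getLogger("twinliab")

NON_ESTIMABLE = "—"

#: Table-2-style zygosity/sex groupings (grouping label -> group selector).
GOF_GROUPINGS: dict[str, str | list[str]] = {
    "Complete pairs": ["MZ", "DZ"],
    "MZ": "MZ",
    "MZf": "MZ-FF",
    "MZm": "MZ-MM",
    "DZ": "DZ",
    "DZss": "DZss",
    "DZf": "DZ-FF",
    "DZm": "DZ-MM",
    "DZos": "DZos",
}

_CLASSIFICATION_LABELS = {
    "minor-only": "Non-depressed, minor depression",
    "major-only": "Non-depressed, major depression",
    "two": "Non-depressed, minor or major depression",
    "three": "Non-depressed, minor depression, major depression",
}


@dataclass
class PipelineConfig:
    """What to analyse and where to put the results."""

    input_path: Optional[str] = None
    preset: Optional[str] = None
    out_dir: str = "twinliab-out"
    seed: int = 0
    classifications: tuple[str, ...] = ("minor-only", "major-only", "two", "three")
    model_ladder: tuple[str, ...] = MODEL_LADDER
    covariates: tuple[str, ...] = ("age", "sex")
    compute_ci: bool = True
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path or preset must be set")


def _fmt(x: Optional[float], digits: int = 2) -> str:
    if x is None:
        return NON_ESTIMABLE
    if x != 0 and abs(x) < 10 ** (-digits):
        return f"{x:.1e}"
    return f"{x:.{digits}f}"


def render_rr_table(records: Sequence[TwinPairRecord]) -> pd.DataFrame:
    """Proband -> co-twin relative risks by zygosity, three-category analysis.

    Rows are proband-condition / co-twin-outcome pairs over minor (MiD),
    major (MD) and their union; columns are MZ, same-sex DZ and the two
    proband orientations of opposite-sex DZ pairs.  Same-sex tables are
    symmetrized before risks are formed.
    """
    conditions = [("MiD", (1,)), ("MD", (2,)), ("MiD/MD", (1, 2))]
    columns: dict[str, object] = {}
    columns["MZ"] = symmetrize(crosstab(records, "MZ", "three"))
    columns["DZss"] = symmetrize(crosstab(records, "DZss", "three"))
    try:
        columns["DZos F–M"] = crosstab(records, "DZos", "three", proband_sex="F")
        columns["DZos M–F"] = crosstab(records, "DZos", "three", proband_sex="M")
    except ValueError:
        pass
    rows = []
    for cname, cond in conditions:
        for oname, outc in conditions:
            row = {"proband-cotwin": f"{cname}−{oname}"}
            for col, table in columns.items():
                row[col] = relative_risk(table, cond, outc).format()
            rows.append(row)
    return pd.DataFrame(rows)


def render_gof_table(records: Sequence[TwinPairRecord]) -> pd.DataFrame:
    """Multiple-threshold model goodness-of-fit p-values per grouping.

    Each grouping's pairs are pooled into a single three-category table
    (the pooled-table variant; thresholds equal across co-twins) and the
    chi-square fit test of the single-liability-continuum model is run.
    """
    rows = []
    for label, selector in GOF_GROUPINGS.items():
        try:
            table = crosstab(records, selector, "three")
            fit = fit_polychoric(table, compute_ci=False)
            p = fit.gof_p
        except ValueError:
            p = None
        rows.append({"Twin pair": label, "GOF p": _fmt(p)})
    return pd.DataFrame(rows)


def render_polychoric_table(records: Sequence[TwinPairRecord]) -> pd.DataFrame:
    """Polychoric correlations (95% CI) per classification for MZ and DZ pairs."""
    rows = []
    for rule, label in _CLASSIFICATION_LABELS.items():
        row = {"Depression classification": label}
        for zyg in ("MZ", "DZ"):
            try:
                table = crosstab(records, zyg, rule)
                row[zyg] = fit_polychoric(table).format()
            except ValueError:
                row[zyg] = NON_ESTIMABLE
        rows.append(row)
    return pd.DataFrame(rows)


def render_model_table(
    records: Sequence[TwinPairRecord],
    classifications: Sequence[str] = ("minor-only", "major-only", "two", "three"),
    ladder: Sequence[str] = MODEL_LADDER,
    covariates: tuple[str, ...] = ("age", "sex"),
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Variance-component model ladder: fit statistics and estimates.

    For each classification, every model in the ladder is fitted and
    compared against the ACE and ADE full models by likelihood-ratio
    test; estimates are variance proportions with profile CIs.
    """
    rows = []
    for rule in classifications:
        k = 2 if rule in ("two", "minor-only", "major-only") else 3
        fits = {}
        for model in ladder:
            spec = ModelSpec(model, covariates=covariates, n_categories=k)
            fits[model] = fit_model(records, spec, collapse=rule, compute_ci=compute_ci)
        for model in ladder:
            f = fits[model]
            row = {"classification": _CLASSIFICATION_LABELS[rule], "model": model}
            row["-2LL"] = f"{f.minus2LL:.2f}"
            for full_name in ("ACE", "ADE"):
                key = f"p ({full_name})"
                if (full_name in fits and model not in ("ACE", "ADE")
                        and f.spec.is_nested_in(fits[full_name].spec)):
                    row[key] = _fmt(likelihood_ratio_test(fits[full_name], f).p)
                else:
                    row[key] = NON_ESTIMABLE
            row["AIC"] = f"{f.aic:.2f}"
            for comp, key in (("A", "a2"), ("C/D", "c2"), ("E", "e2")):
                est_key = "d2" if (key == "c2" and "D" in f.spec.components) else key
                if est_key == "e2" or est_key[0].upper() in f.spec.components:
                    val = f.estimates[est_key]
                    ci = f.ci.get(est_key)
                    row[comp] = (f"{val:.2f} ({ci[0]:.2f}–{ci[1]:.2f})" if ci else f"{val:.2f}")
                else:
                    row[comp] = NON_ESTIMABLE
            rows.append(row)
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, out_dir: Path, name: str) -> dict[str, str]:
    tsv = out_dir / f"{name}.tsv"
    js = out_dir / f"{name}.json"
    df.to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(df.to_dict(orient="records"), ensure_ascii=False, indent=1))
    return {"tsv": str(tsv), "json": str(js)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain; returns tables and output paths.

    Stages run in order (relative risks, liability-model fit, model
    ladder); a stage failure aborts with the stage name while earlier
    outputs are preserved on disk.
    """
    t_start = time.time()
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbose else logging.WARNING,
        format="%(name)s %(levelname)s %(message)s",
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.preset is not None:
        params = preset_params(config.preset, seed=config.seed)
        records = simulate_cohort(params)
        write_twin_table(records, out_dir / "cohort.tsv")
        source = f"preset:{config.preset}"
    else:
        result = read_twin_table(config.input_path)
        if result.errors:
            log.warning("%d malformed rows rejected", len(result.errors))
        records = result.records
        source = str(config.input_path)

    outputs: dict = {"tables": {}, "paths": {}}
    stages = [
        ("relative_risks", lambda: render_rr_table(records)),
        ("liability_gof", lambda: render_gof_table(records)),
        ("polychoric", lambda: render_polychoric_table(records)),
        ("model_ladder", lambda: render_model_table(
            records, config.classifications, config.model_ladder,
            config.covariates, config.compute_ci)),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            df = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        outputs["tables"][name] = df
        outputs["paths"][name] = _write_table(df, out_dir, name)
        log.info("stage %s done in %.1fs", name, time.time() - t0)

    manifest = {
        "twinliab_version": __version__,
        "seed": config.seed,
        "source": source,
        "n_pairs": len(records),
        "classifications": list(config.classifications),
        "model_ladder": list(config.model_ladder),
        "covariates": list(config.covariates),
        "numpy_version": np.__version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = manifest
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return outputs
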