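"""End-to-end orchestration: generate -> cohort -> classify -> evaluate.

A run is a pure function of its :class:`~oacphen.config.RunConfig`:
re-running with the same config (same seed) reproduces every output file
byte for byte. The manifest records seed, config hash and package version
so a run can be re-executed from its own provenance.

A ``from-counts`` mode evaluates test characteristics directly from a CSV
of 2x2 counts, decoupling the metric arithmetic from simulation — this is
how the reported validation counts are re-evaluated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

import oacphen
from oacphen.algorithms import builtin_algorithms, classify_cohort, get_algorithm
from oacphen.cohort import apply_vte_exclusion, build_cohort
from oacphen.config import RunConfig
from oacphen.errors import ConfigurationError, DataError
from oacphen.metrics import Counts2x2, evaluate, tabulate
from oacphen.published import SECTION_PLAIN, published_table
from oacphen.simulate import generate_population
from oacphen.tables_io import write_tables

log = logging.getLogger("oacphen")

RESULT_COLUMNS = [
    "algo_id", "window", "section", "n", "tp", "tn", "fp", "fn",
    "sens", "sens_lo", "sens_hi", "spec", "spec_lo", "spec_hi",
    "ppv", "ppv_lo", "ppv_hi", "npv", "npv_lo", "npv_hi", "rate_percent",
]

_SECTIONS = published_table().set_index("algo_id")["section"].to_dict()


def _result_row(res, spec=None) -> dict:
    row = res.to_row()
    row["n"] = res.counts.n
    if spec is not None:
        row["window"] = spec.window_label
        row["section"] = _SECTIONS.get(spec.algo_id, SECTION_PLAIN)
    else:
        row.setdefault("window", "")
        row.setdefault("section", "")
    return row


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        json.loads(config.model_dump_json()), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_validation(
    config: RunConfig, output_directory: Optional[Path] = None
) -> pd.DataFrame:
    """Run the whole validation and write results.csv + run_manifest.json.

    Returns the results table (one row per algorithm, display-rounded).
    """
    out = Path(output_directory or config.output_directory)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating %d patients (seed %d)", config.simulation.n_patients,
             config.simulation.seed)
    tables = generate_population(config.simulation)
    write_tables(tables, out / "tables")
    log.info("generated %d ED visits, %d drug claims, %d outpatient visits",
             len(tables.ed_visits), len(tables.drug_claims),
             len(tables.outpatient_visits))

    cohort = build_cohort(tables, config.cohort)
    cohort_out = cohort.copy()
    from oacphen.dates import day_to_iso

    cohort_out["index_departure_date"] = cohort_out["index_departure_date"].map(day_to_iso)
    cohort_out.to_csv(out / "cohort.csv", index=False, lineterminator="\n")
    n_vte = int(cohort["vte_within_5y"].sum()) if len(cohort) else 0
    log.info("cohort: %d eligible patients (%d with 5y VTE history)",
             len(cohort), n_vte)

    rows = []
    for algo_id in config.algorithm_ids:
        spec = get_algorithm(algo_id)
        pred = classify_cohort(cohort, tables, spec)
        pred_out = pred.copy()
        pred_out["qualifying_fill_date"] = pred_out["qualifying_fill_date"].map(
            lambda d: "" if pd.isna(d) else day_to_iso(d)
        )
        pred_out.to_csv(out / f"predictions_{algo_id}.csv", index=False,
                        lineterminator="\n")
        ref = apply_vte_exclusion(cohort) if spec.vte_exclusion else cohort
        counts = tabulate(pred, ref)
        rows.append(_result_row(evaluate(counts, algo_id), spec))
        log.info("algorithm %d: %d/%d positive", algo_id,
                 counts.tp + counts.fp, counts.n)

    results = pd.DataFrame(rows)[RESULT_COLUMNS]
    results.to_csv(out / "results.csv", index=False, lineterminator="\n")

    manifest = {
        "package": "oacphen",
        "version": oacphen.__version__,
        "seed": config.simulation.seed,
        "config_hash": config_hash(config),
        "config": json.loads(config.model_dump_json()),
        "n_patients": config.simulation.n_patients,
        "n_cohort": len(cohort),
        "n_cohort_vte_excluded": len(cohort) - n_vte,
        "algorithms": list(config.algorithm_ids),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n"
    )
    return results


def evaluate_from_counts(counts: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Evaluate metrics from a table of 2x2 counts.

    Accepts a frame (or CSV path) with columns ``algo_id, tp, tn, fp, fn``;
    returns the same results table layout as :func:`run_validation`.
    """
    if not isinstance(counts, pd.DataFrame):
        path = Path(counts)
        if not path.exists():
            raise DataError(f"counts file not found: {path}")
        counts = pd.read_csv(path)
    required = {"algo_id", "tp", "tn", "fp", "fn"}
    missing = required - set(counts.columns)
    if missing:
        raise DataError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for rec in counts.itertuples(index=False):
        c = Counts2x2(tp=int(rec.tp), tn=int(rec.tn), fp=int(rec.fp), fn=int(rec.fn))
        algo_id = int(rec.algo_id)
        spec = get_algorithm(algo_id) if 1 <= algo_id <= 32 else None
        rows.append(_result_row(evaluate(c, algo_id), spec))
    return pd.DataFrame(rows)[RESULT_COLUMNS]


def render_table(results: pd.DataFrame) -> str:
    """Render a results table as fixed-width text grouped by section."""
    if results is None or len(results) == 0:
        raise ConfigurationError("no results to render")
    lines = []
    header = (
        f"{'No.':>3}  {'Days':>5}  {'TP':>5} {'TN':>5} {'FP':>5} {'FN':>5}  "
        f"{'Sens (95% CI)':>21}  {'Spec (95% CI)':>21}  "
        f"{'PPV (95% CI)':>21}  {'NPV (95% CI)':>21}  {'Rate,%':>6}"
    )

    def _ci(row, name):
        if pd.isna(row[name]):
            return "--"
        return f"{row[name]:.3f} ({row[f'{name}_lo']:.3f}-{row[f'{name}_hi']:.3f})"

    for section in results["section"].unique():
        block = results[results["section"] == section]
        lines.append(f"== {section} ==" if section else "== Results ==")
        lines.append(header)
        for _, row in block.iterrows():
            rate = "--" if pd.isna(row["rate_percent"]) else f"{row['rate_percent']:.1f}"
            lines.append(
                f"{row['algo_id']:>3}  {row['window']:>5}  "
                f"{row['tp']:>5} {row['tn']:>5} {row['fp']:>5} {row['fn']:>5}  "
                f"{_ci(row, 'sens'):>21}  {_ci(row, 'spec'):>21}  "
                f"{_ci(row, 'ppv'):>21}  {_ci(row, 'npv'):>21}  {rate:>6}"
            )
        lines.append("")
    return "\n".join(lines)


def published_counts_frame(vte_excluded: bool | None = None) -> pd.DataFrame:
    """The reported 2x2 counts in ``from-counts`` input layout."""
    df = published_table()[["algo_id", "tp", "tn", "fp", "fn", "vte_exclusion"]]
    if vte_excluded is not None:
        df = df[df["vte_exclusion"] == vte_excluded]
    return df.drop(columns="vte_exclusion").reset_index(drop=True)
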