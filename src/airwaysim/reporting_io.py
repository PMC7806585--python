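"""Report writers tying the pipeline stages together.

Every report is deterministic text (CSV/JSON) carrying a provenance header
(config hash, seed, package version) so re-running a configuration
reproduces it byte for byte.  Fractions are reported both as fractions and
as percentages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .aerosol import DepositionRecord, regional_DE, total_DE
from .config import config_hash
from .flow_network import FlowSolution
from .morphometry import REGIONS, LOBES, AirwayTree

log = logging.getLogger("airwaysim")


@dataclass
class RunConfig:
    """Validated configuration plus output bookkeeping for one run."""

    cfg: dict
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.cfg)


def provenance_header(run: RunConfig) -> str:
    return f"# airwaysim={__version__} config_sha256={run.hash} seed={run.seed}\n"


def _write_csv(df: pd.DataFrame, path: str, run: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(run))
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def write_flow_report(sols: list[FlowSolution], tree: AirwayTree, path: str, run: RunConfig) -> None:
    rows = []
    for sol in sols:
        for bid in tree.branches:
            rows.append(
                {
                    "time_s": sol.time,
                    "branch_id": bid,
                    "flow_lpm": sol.branch_flow[bid],
                    "velocity_mps": sol.branch_velocity[bid],
                    "reynolds": sol.branch_reynolds[bid],
                }
            )
    _write_csv(pd.DataFrame(rows), path, run)


def write_node_pressures(sols: list[FlowSolution], path: str, run: RunConfig) -> None:
    rows = []
    for sol in sols:
        for node, p in sol.node_pressure.items():
            rows.append({"time_s": sol.time, "node": node, "pressure_pa": p})
    _write_csv(pd.DataFrame(rows), path, run)


def deposition_table(record: DepositionRecord) -> pd.DataFrame:
    rows = []
    for region in REGIONS:
        de = regional_DE(record, region)
        rows.append(
            {
                "region": region,
                "entering_fraction": record.per_region_entering.get(region, 0.0),
                "deposited_fraction": record.deposited.get(region, 0.0),
                "deposited_percent": 100.0 * record.deposited.get(region, 0.0),
                "DE": "" if de is None else de,
                "DE_percent": "" if de is None else 100.0 * de,
            }
        )
    return pd.DataFrame(rows)


def lobe_escape_table(record: DepositionRecord) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lobe": lobe, "escaped_fraction": record.escaped.get(lobe, 0.0), "escaped_percent": 100.0 * record.escaped.get(lobe, 0.0)}
            for lobe in LOBES
        ]
    )


def write_deposition_report(record: DepositionRecord, path: str, run: RunConfig) -> None:
    _write_csv(deposition_table(record), path, run)


def write_lobe_escape_report(record: DepositionRecord, path: str, run: RunConfig) -> None:
    _write_csv(lobe_escape_table(record), path, run)


def record_summary(record: DepositionRecord) -> dict:
    return {
        "deposited": record.deposited,
        "escaped": record.escaped,
        "suspended": record.suspended,
        "exhaled": record.exhaled,
        "per_region_entering": record.per_region_entering,
        "total_DE": total_DE(record),
        "total_DE_percent": 100.0 * total_DE(record),
        "conservation_residual": record.conservation_residual(),
    }


def write_summary_json(payload: dict, path: str, run: RunConfig) -> None:
    out = {"airwaysim": __version__, "config_sha256": run.hash, "seed": run.seed, **payload}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        return float(obj)
    except (TypeError, ValueError):
        return str(obj)


# ---- figure-equivalent tables ---------------------------------------------

def de_by_size_table(records_by_size: dict[float, DepositionRecord]) -> pd.DataFrame:
    """One row per (particle size, region): deposited fraction and regional DE."""
    rows = []
    for size, rec in sorted(records_by_size.items()):
        for region in REGIONS:
            de = regional_DE(rec, region)
            rows.append(
                {
                    "dp_um": size,
                    "region": region,
                    "deposited_fraction": rec.deposited.get(region, 0.0),
                    "DE": "" if de is None else de,
                    "DE_percent": "" if de is None else 100.0 * de,
                }
            )
        rows.append(
            {
                "dp_um": size,
                "region": "total",
                "deposited_fraction": total_DE(rec),
                "DE": total_DE(rec),
                "DE_percent": 100.0 * total_DE(rec),
            }
        )
    return pd.DataFrame(rows)


def de_vs_transport_number_table(records_by_size: dict[float, tuple[dict, DepositionRecord]]) -> pd.DataFrame:
    """DE against the transport number that governs it per region:
    impaction parameter upstream, Stokes number in the tracheobronchial tree."""
    rows = []
    for size, (numbers, rec) in sorted(records_by_size.items()):
        for region in REGIONS:
            de = regional_DE(rec, region)
            if de is None:
                continue
            rows.append(
                {
                    "dp_um": size,
                    "region": region,
                    "transport_number": numbers.get(region, ""),
                    "kind": "IP" if region in ("oral", "pharynx", "larynx") else "St",
                    "DE": de,
                    "DE_percent": 100.0 * de,
                }
            )
    return pd.DataFrame(rows)


def sweep_table(sweep: list[tuple[float, DepositionRecord]]) -> pd.DataFrame:
    rows = []
    for t_inj, rec in sweep:
        row = {"t_inj_s": t_inj, "total_DE": total_DE(rec), "total_DE_percent": 100.0 * total_DE(rec), "suspended_fraction": rec.suspended}
        for region in REGIONS:
            de = regional_DE(rec, region)
            row[f"DE_{region}"] = "" if de is None else de
        for lobe in LOBES:
            row[f"escaped_{lobe}"] = rec.escaped.get(lobe, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def steady_vs_transient_table(comparison: dict) -> pd.DataFrame:
    rows = [
        {"case": "steady", "total_DE": comparison["steady"]["total_DE"], "total_DE_percent": 100.0 * comparison["steady"]["total_DE"]},
        {
            "case": "transient_cycle_mean",
            "total_DE": comparison["transient"]["total_DE_cycle_mean"],
            "total_DE_percent": 100.0 * comparison["transient"]["total_DE_cycle_mean"],
        },
        {
            "case": f"transient_best_tinj_{comparison['transient']['best_t_inj']}s",
            "total_DE": comparison["transient"]["total_DE_best"],
            "total_DE_percent": 100.0 * comparison["transient"]["total_DE_best"],
        },
    ]
    return pd.DataFrame(rows)


def log_conservation(stage: str, record: DepositionRecord) -> None:
    log.info("%s: conservation residual %.3e (deposited %.4f escaped %.4f suspended %.4f)",
             stage, record.conservation_residual(), record.total_deposited, record.total_escaped, record.suspended)
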