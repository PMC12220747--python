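"""Pipeline runner and table/report writers (CSV, markdown, JSON)."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from hashlib import sha256
from pathlib import Path
from typing import Optional, Sequence, Union

from .engine import CATEGORY_ORDER
from .model import PrEPDeliveryCostModel, _ROW_LABELS
from .scenarios import Scenario

__all__ = ["RunConfig", "run_pipeline", "render_tables", "markdown_table"]

logger = logging.getLogger("prepcost")

FORMATS = ("csv", "markdown", "json")


@dataclass
class RunConfig:
    """Configuration for one end-to-end costing run."""

    ledger_path: Path
    accruals_path: Path
    observations_path: Optional[Path] = None
    scenario: Optional[Scenario] = None
    output_dir: Path = Path("prepcost_out")
    formats: tuple[str, ...] = ("json", "markdown")
    log_level: str = "INFO"

    def __post_init__(self):
        self.ledger_path = Path(self.ledger_path)
        self.accruals_path = Path(self.accruals_path)
        if self.observations_path is not None:
            self.observations_path = Path(self.observations_path)
        self.output_dir = Path(self.output_dir)
        for f in self.formats:
            if f not in FORMATS:
                raise ValueError(f"unknown output format {f!r}")


def _digest(path: Path) -> str:
    return sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full costing pipeline and return the report bundle.

    The bundle is a plain JSON-serializable dict: per-arm category tables,
    unit costs, shares, and the arm comparison.  Identical inputs produce a
    byte-identical serialized bundle.
    """
    logging.basicConfig(level=config.log_level)
    for path in (config.ledger_path, config.accruals_path, config.observations_path):
        if path is not None and not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        if path is not None:
            logger.info("input %s sha256=%s", path, _digest(path))
    model = PrEPDeliveryCostModel.from_files(
        ledger_path=config.ledger_path,
        accruals_path=config.accruals_path,
        observations_path=config.observations_path,
        scenario=config.scenario,
    )
    results = model.fit()
    bundle = results.to_dict()
    logger.info(
        "scenario=%s soc_unit_cost=%s intervention_unit_cost=%s",
        bundle["scenario"],
        bundle["comparison"]["soc_unit_cost"],
        bundle["comparison"]["intervention_unit_cost"],
    )
    return bundle


def markdown_table(header: Sequence[str], rows: Sequence[Sequence]) -> str:
    cells = [[str(c) for c in row] for row in rows]
    widths = [max(len(h), *(len(r[i]) for r in cells)) if cells else len(h)
              for i, h in enumerate(header)]
    def fmt(row):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |"
    out = [fmt(list(header)), "| " + " | ".join("-" * w for w in widths) + " |"]
    out += [fmt(r) for r in cells]
    return "\n".join(out)


def _cost_table_rows(bundle: dict) -> tuple[list[str], list[list[str]]]:
    arms = bundle["arms"]
    header = ["Cost category"]
    for arm in ("soc", "intervention"):
        label = "SOC" if arm == "soc" else "Six-month PrEP + HIVST"
        header += [f"{label} annual", f"{label} $/client-month", f"{label} %"]
    rows = []
    for cat in CATEGORY_ORDER:
        row = [_ROW_LABELS[cat]]
        for arm in ("soc", "intervention"):
            a = arms[arm]
            share = float(a["shares"][cat.value])
            row += [a["category_totals"][cat.value], a["unit_costs"][cat.value],
                    f"{round(share * 100)}%"]
        rows.append(row)
    total_row = ["Total"]
    for arm in ("soc", "intervention"):
        a = arms[arm]
        total_row += [a["grand_total"], a["unit_cost_total"], "100%"]
    rows.append(total_row)
    return header, rows


def render_tables(bundle: dict, output_dir: Union[str, Path], fmt: str) -> list[Path]:
    """Write the report bundle as files in the requested format.

    Row order mirrors the published cost tables; currency to cents, shares as
    whole percents.  The JSON rendering round-trips to the same bundle.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; choose from {FORMATS}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    scenario = bundle["scenario"]
    written: list[Path] = []
    if fmt == "json":
        path = output_dir / f"costs_{scenario}.json"
        path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
        return [path]
    header, rows = _cost_table_rows(bundle)
    comp_header = ["scenario", "soc_unit_cost", "intervention_unit_cost",
                   "abs_difference", "pct_difference"]
    comp = bundle["comparison"]
    comp_row = [scenario, comp["soc_unit_cost"], comp["intervention_unit_cost"],
                comp["abs_difference"], f"{comp['pct_difference']}%"]
    if fmt == "csv":
        path = output_dir / f"costs_{scenario}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerows(rows)
        written.append(path)
        path = output_dir / f"comparison_{scenario}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(comp_header)
            writer.writerow(comp_row)
        written.append(path)
    else:  # markdown
        path = output_dir / f"costs_{scenario}.md"
        text = (
            f"# Annual PrEP delivery costs — {scenario} scenario (2019 USD)\n\n"
            + markdown_table(header, rows)
            + "\n\n"
            + markdown_table(comp_header, [comp_row])
            + "\n"
        )
        path.write_text(text)
        written.append(path)
    return written
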