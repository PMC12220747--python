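"""Packaged cost-input fixtures.

Three ledgers ship with the package, encoding the published 2019 Kenya
study inputs:

* ``trial_2019`` — as-implemented research-clinic delivery,
* ``moh_2019`` — projected public-clinic (Ministry of Health) delivery,
* ``moh_creatinine_2019`` — public-clinic delivery with bi-annual serum
  creatinine testing (equals ``moh_2019`` with the creatinine scenario
  applied).

Per-visit clinical-personnel rates, laboratory consumable residuals, and the
procurement-inclusive drug prices in these files are *calibrated*: they are
back-solved from the published annual category totals because the underlying
expense reports are not public.  The mechanistic route (time-and-motion
minutes x wages) remains available for ledgers without per-visit personnel
lines.  One shared accrual fixture covers both scenarios.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .ledger import Arm, ArmAccrual, Ledger, load_accruals, load_ledger

__all__ = ["fixture_path", "load_fixture_ledger", "load_fixture_accruals", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("trial", "moh", "moh_creatinine")

_FILES = {
    "trial": "trial_2019.yaml",
    "moh": "moh_2019.yaml",
    "moh_creatinine": "moh_creatinine_2019.yaml",
    "accruals": "accruals_2019.yaml",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (``trial``, ``moh``,
    ``moh_creatinine``, or ``accruals``)."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}") from None
    return Path(resources.files("prepcost").joinpath("data", fname))


def load_fixture_ledger(name: str) -> Ledger:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown ledger fixture {name!r}; choose from {FIXTURE_NAMES}")
    return load_ledger(fixture_path(name))


def load_fixture_accruals() -> dict[Arm, ArmAccrual]:
    return load_accruals(fixture_path("accruals"))
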