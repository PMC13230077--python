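"""Report tables (cost ledger, ICER summary) and the run manifest.

Tabular outputs mirror the familiar base-case reporting layout of
cost-utility analyses: a per-category discounted cost ledger per strategy
with an incremental column, and an ICER summary per perspective.  THB
values are rounded to the nearest baht and USD columns are derived from
the fixed reporting exchange rate; life-years and QALYs print at 4
decimals.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import StrategyComparison, to_usd
from .params import AnalysisSettings, ModelParameters, canonical_config_text

LEDGER_LABELS = {
    "drug_statin": "Cost of moderate-intensity statin",
    "drug_ez": "Cost of ezetimibe",
    "acs_y1": "ACS first year",
    "acs_y2plus": "ACS second year and onward",
    "mi_y1": "Non-fatal MI first year",
    "mi_y2plus": "Non-fatal MI second year and onward",
    "stroke_y1": "Non-fatal stroke first year",
    "stroke_y2plus": "Non-fatal stroke second year and onward",
    "dnm_y1": "Direct non-medical cost first year",
    "dnm_y2plus": "Direct non-medical cost second year and onward",
}

_DNM_KEYS = ("dnm_y1", "dnm_y2plus")


def ledger_table(comparison: StrategyComparison,
                 settings: AnalysisSettings,
                 perspective: str | None = None) -> pd.DataFrame:
    """Per-category discounted cost ledger with incremental column.

    Under the provider perspective the direct non-medical rows are
    omitted.  Appends total-cost, life-year and QALY summary rows.
    """
    perspective = perspective or settings.perspective
    ref, alt = comparison.comparator, comparison.intervention
    rows = []
    for key, label in LEDGER_LABELS.items():
        if perspective == "provider" and key in _DNM_KEYS:
            continue
        a = ref.ledger.as_dict()[key]
        b = alt.ledger.as_dict()[key]
        rows.append({
            "category": label,
            "statin_alone_thb": round(a),
            "ezetimibe_plus_statin_thb": round(b),
            "incremental_thb": round(b - a),
            "statin_alone_usd": round(to_usd(a, settings), 1),
            "ezetimibe_plus_statin_usd": round(to_usd(b, settings), 1),
            "incremental_usd": round(to_usd(b - a, settings), 1),
        })
    ta, tb = ref.ledger.total(perspective), alt.ledger.total(perspective)
    rows.append({
        "category": f"Total cost ({perspective} perspective)",
        "statin_alone_thb": round(ta),
        "ezetimibe_plus_statin_thb": round(tb),
        "incremental_thb": round(tb - ta),
        "statin_alone_usd": round(to_usd(ta, settings), 1),
        "ezetimibe_plus_statin_usd": round(to_usd(tb, settings), 1),
        "incremental_usd": round(to_usd(tb - ta, settings), 1),
    })
    for label, a, b in (("LYs", ref.life_years, alt.life_years),
                        ("QALYs", ref.qalys, alt.qalys)):
        rows.append({
            "category": label,
            "statin_alone_thb": round(a, 4),
            "ezetimibe_plus_statin_thb": round(b, 4),
            "incremental_thb": round(b - a, 4),
            "statin_alone_usd": None,
            "ezetimibe_plus_statin_usd": None,
            "incremental_usd": None,
        })
    return pd.DataFrame(rows)


def icer_table(comparison: StrategyComparison,
               settings: AnalysisSettings) -> pd.DataFrame:
    """ICER summary, one row per perspective, THB and USD columns."""
    rows = []
    for perspective, res in comparison.icers.items():
        rows.append({
            "perspective": perspective,
            "delta_cost_thb": round(res.delta_cost),
            "delta_cost_usd": round(to_usd(res.delta_cost, settings), 1),
            "delta_ly": round(res.delta_ly, 4),
            "delta_qaly": round(res.delta_qaly, 4),
            "icer_thb_per_ly": None if res.icer_per_ly is None
            else round(res.icer_per_ly),
            "icer_thb_per_qaly": None if res.icer_per_qaly is None
            else round(res.icer_per_qaly),
            "icer_usd_per_qaly": None if res.icer_per_qaly is None
            else round(to_usd(res.icer_per_qaly, settings), 1),
            "flag": res.flag or "",
            "cost_effective_at_wtp": res.cost_effective_at_wtp,
            "wtp_thb_per_qaly": settings.wtp,
        })
    return pd.DataFrame(rows)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def build_manifest(params: ModelParameters,
                   settings: AnalysisSettings,
                   life_table_path: str | Path | None,
                   seed: int | None = None,
                   extra: dict | None = None) -> dict:
    """Provenance record written alongside every set of output files."""
    config_text = canonical_config_text(params, settings)
    lt_hash = None
    if life_table_path is not None:
        lt_hash = _sha256(Path(life_table_path).read_text())
    manifest = {
        "software": "acscea",
        "version": __version__,
        "config_sha256": _sha256(config_text),
        "life_table_sha256": lt_hash,
        "life_table_path": None if life_table_path is None
        else str(life_table_path),
        "settings": settings.to_dict(),
        "seed": seed,
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
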