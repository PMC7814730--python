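"""Evaluation of structural alerts on labeled compound sets.

Each alert (mined or external, e.g. literature toxicophores) is matched
aromaticity-aware against the standardized compounds; precision
TP/(TP+FP), percentage coverage among DILI positives, and a one-sided
(greater) Fisher exact p on the 2×2 matched/unmatched × DILI/NoDILI table
are reported, with significance at p ≤ 0.05 (inclusive, uncorrected — a BH
option exists but is off by default). Alerts can additionally be screened
against an approved-drug catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .interpret import benjamini_hochberg

SIGNIFICANCE_LEVEL = 0.05


def _compile(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
    return query


def match(pattern: str, smiles_list: Sequence[str], ids: Sequence[str] | None = None) -> list[str]:
    """Ids of compounds containing the SMARTS pattern as a substructure."""
    query = _compile(pattern)
    if ids is None:
        ids = [str(i) for i in range(len(smiles_list))]
    out = []
    for cid, smi in zip(ids, smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {cid}: {smi!r}")
        if mol.HasSubstructMatch(query):
            out.append(cid)
    return out


@dataclass(frozen=True)
class AlertMetrics:
    pattern: str
    source: str
    tp: int
    fp: int
    precision: float | None  # None when the alert matches nothing
    coverage: float  # percent of DILI positives matched
    fisher_p: float
    significant: bool
    catalog_hits: int = 0
    catalog_examples: tuple[str, ...] = ()


def evaluate_alert(
    pattern: str,
    smiles_list: Sequence[str],
    labels: Sequence[int],
    source: str = "external",
) -> AlertMetrics:
    """Precision, coverage and Fisher-exact significance of one alert.

    An alert matching nothing has undefined precision (emitted as None),
    coverage 0 and p = 1.
    """
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation set must contain both classes")
    query = _compile(pattern)
    matched = np.array(
        [Chem.MolFromSmiles(s).HasSubstructMatch(query) for s in smiles_list]
    )
    tp = int((matched & (labels == 1)).sum())
    fp = int((matched & (labels == 0)).sum())
    table = [[tp, fp], [n_pos - tp, n_neg - fp]]
    _, p = stats.fisher_exact(table, alternative="greater")
    precision = tp / (tp + fp) if tp + fp else None
    return AlertMetrics(
        pattern=pattern,
        source=source,
        tp=tp,
        fp=fp,
        precision=precision,
        coverage=100.0 * tp / n_pos,
        fisher_p=float(p),
        significant=bool(p <= SIGNIFICANCE_LEVEL),
    )


def evaluate_alerts(
    patterns: Sequence[tuple[str, str]],
    smiles_list: Sequence[str],
    labels: Sequence[int],
    adjust: bool = False,
) -> list[AlertMetrics]:
    """Evaluate (pattern, source) pairs; optional BH adjustment of the
    Fisher p-values (off by default — the alerts are reported uncorrected)."""
    out = [evaluate_alert(p, smiles_list, labels, source=s) for p, s in patterns]
    if adjust and out:
        q = benjamini_hochberg(np.array([m.fisher_p for m in out]))
        out = [
            AlertMetrics(
                m.pattern, m.source, m.tp, m.fp, m.precision, m.coverage,
                float(qv), bool(qv <= SIGNIFICANCE_LEVEL),
                m.catalog_hits, m.catalog_examples,
            )
            for m, qv in zip(out, q)
        ]
    return out


def catalog_screen(
    metrics: Sequence[AlertMetrics],
    catalog_smiles: Sequence[str],
    catalog_ids: Sequence[str],
    n_examples: int = 3,
) -> list[AlertMetrics]:
    """Count approved-catalog compounds matching each alert.

    The catalog is expected to be standardized by the curation module
    already. Returns new metrics records with catalog hit counts and a few
    exemplar compound ids filled in.
    """
    mols = [(cid, Chem.MolFromSmiles(s)) for cid, s in zip(catalog_ids, catalog_smiles)]
    out = []
    for m in metrics:
        query = _compile(m.pattern)
        hits = [cid for cid, mol in mols if mol is not None and mol.HasSubstructMatch(query)]
        out.append(
            AlertMetrics(
                m.pattern, m.source, m.tp, m.fp, m.precision, m.coverage,
                m.fisher_p, m.significant,
                catalog_hits=len(hits),
                catalog_examples=tuple(hits[:n_examples]),
            )
        )
    return out


def summarize_alerts(metrics: Sequence[AlertMetrics], significant_only: bool = True) -> pd.DataFrame:
    """Per-source summary: mean ± sd precision and coverage, catalog range.

    Sample standard deviation (ddof=1); a single alert reports sd 0. Alerts
    with undefined precision (no matches) are excluded from the precision
    aggregate but retained in the counts.
    """
    rows = []
    pool = [m for m in metrics if m.significant] if significant_only else list(metrics)
    for source in sorted({m.source for m in pool}):
        ms = [m for m in pool if m.source == source]
        precisions = [m.precision for m in ms if m.precision is not None]
        coverages = [m.coverage for m in ms]
        catalog = [m.catalog_hits for m in ms]

        def _sd(vals):
            return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

        rows.append(
            {
                "source": source,
                "n_alerts": len(ms),
                "mean_precision": float(np.mean(precisions)) if precisions else None,
                "sd_precision": _sd(precisions),
                "mean_coverage_pct": float(np.mean(coverages)),
                "sd_coverage_pct": _sd(coverages),
                "min_catalog_presence": int(min(catalog)) if catalog else 0,
                "max_catalog_presence": int(max(catalog)) if catalog else 0,
            }
        )
    return pd.DataFrame(rows)
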