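"""Label-free bait-interactome (volcano) analysis.

Protein-group tables carry one intensity column per replicate per group
(``intensity.<group>.<replicate>``; MaxQuant-style names accepted via a
column mapping).  Analysis: filter rows by valid-value counts, log2-transform,
per-protein unpaired Student's t-test of bait vs control, log2 fold change of
group means, significance at p < α with positive fold change.  No imputation,
no multiple-testing correction of the significance flag (a Benjamini-Hochberg
FDR column is emitted for reference only).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BAIT_GROUP = "bait"
CONTROL_GROUP = "control"
_INTENSITY_RE = re.compile(r"^intensity\.(?P<group>[^.]+)\.(?P<rep>\d+)$")


def intensity_columns(table: pd.DataFrame) -> dict[str, list[str]]:
    """Map group name → ordered list of its intensity columns."""
    groups: dict[str, list[str]] = {}
    for col in table.columns:
        m = _INTENSITY_RE.match(col)
        if m:
            groups.setdefault(m.group("group"), []).append(col)
    for cols in groups.values():
        cols.sort(key=lambda c: int(c.rsplit(".", 1)[1]))
    return groups


def read_lfq_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated protein-group table.

    ``column_map`` renames foreign (e.g. MaxQuant ``LFQ intensity <sample>``)
    columns to the canonical ``intensity.<group>.<replicate>`` scheme.
    """
    table = pd.read_csv(path, sep="\t")
    if column_map:
        missing = [c for c in column_map if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: column_map refers to missing columns: {missing}")
        table = table.rename(columns=column_map)
    if "protein_id" not in table.columns:
        raise ValueError(f"{path}: missing required column 'protein_id'")
    groups = intensity_columns(table)
    if BAIT_GROUP not in groups or CONTROL_GROUP not in groups:
        raise ValueError(
            f"{path}: need intensity columns for groups {BAIT_GROUP!r} and {CONTROL_GROUP!r}; "
            f"found {sorted(groups)}"
        )
    if len(groups[BAIT_GROUP]) != len(groups[CONTROL_GROUP]):
        raise ValueError(f"{path}: unequal replicate counts per group")
    return table


def filter_quantifiable(table: pd.DataFrame, min_valid_per_group: int = 2) -> pd.DataFrame:
    """Keep rows with at least ``min_valid_per_group`` present values in each group."""
    groups = intensity_columns(table)
    keep = pd.Series(True, index=table.index)
    for group, cols in groups.items():
        keep &= table[cols].notna().sum(axis=1) >= min_valid_per_group
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_quantifiable: removed %d rows (<%d valid values in a group)", removed, min_valid_per_group)
    return table[keep].reset_index(drop=True)


def volcano(table: pd.DataFrame, alpha: float = 0.05, sign_sensitive: bool = True) -> pd.DataFrame:
    """Per-protein volcano statistics on log2-transformed intensities.

    ``log2_fc = mean(log2 bait) − mean(log2 control)``; p from the unpaired
    two-sample Student's t-test on the log2 values (pooled variance, NaNs
    dropped per row).  ``significant`` ⇔ p < α, and additionally log2_fc > 0
    when ``sign_sensitive`` (enriched-in-bait classification).
    """
    groups = intensity_columns(table)
    bait = np.log2(table[groups[BAIT_GROUP]].to_numpy(dtype=float))
    ctrl = np.log2(table[groups[CONTROL_GROUP]].to_numpy(dtype=float))

    n1 = np.sum(~np.isnan(bait), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(bait, axis=1)
        m2 = np.nanmean(ctrl, axis=1)
        v1 = np.nanvar(bait, axis=1, ddof=1)
        v2 = np.nanvar(ctrl, axis=1, ddof=1)
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
        p = 2.0 * sps.t.sf(np.abs(t), df)

    log2_fc = m1 - m2
    degenerate = ~np.isfinite(t)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)
    if degenerate.any():
        logger.warning("volcano: %d zero-variance rows set to p=1", int(degenerate.sum()))

    significant = p < alpha
    if sign_sensitive:
        significant &= log2_fc > 0

    out = pd.DataFrame(
        {
            "protein_id": table["protein_id"].to_numpy(),
            "log2_fc": log2_fc,
            "t_statistic": t,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "significant": significant,
            "degenerate": degenerate,
            "n_bait": n1,
            "n_control": n2,
        }
    )
    if "gene_name" in table.columns:
        out.insert(1, "gene_name", table["gene_name"].to_numpy())
    # reference-only FDR column; never drives the significance flag
    out["fdr_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def annotate(rows: pd.DataFrame, annotation_map: dict[str, set[str]]) -> pd.DataFrame:
    """Attach static annotation-set membership flags.

    Adds one boolean column ``flag.<label>`` per annotation label and returns
    the per-label matched counts via an attribute-free log line; ids in the
    map absent from the table are counted and ignored.
    """
    out = rows.copy()
    present = set(out["protein_id"])
    for label, ids in annotation_map.items():
        ids = set(ids)
        unknown = ids - present
        if unknown:
            logger.info("annotate: %d ids for label %r not in table", len(unknown), label)
        out[f"flag.{label}"] = out["protein_id"].isin(ids)
    return out


def annotation_counts(annotated: pd.DataFrame) -> dict[str, int]:
    return {
        col.removeprefix("flag."): int(annotated[col].sum())
        for col in annotated.columns
        if col.startswith("flag.")
    }
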