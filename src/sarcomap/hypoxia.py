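"""Hypoxia gene-signature scoring from qPCR Ct tables.

A tumour's hypoxia score (HS) is the median, over a 24-gene hypoxia
signature, of the control-normalised log2 expression of each gene:

    delta_g = -(Ct_g - mean(Ct_control))        (per sample)
    HS      = median_g(delta_g)

The arithmetic mean of the control-gene Ct values corresponds to the
geometric mean of control-gene expression on the linear scale, so this is
geometric-mean reference normalisation expressed in cycle space. One qPCR
cycle is one log2 unit: delta_g = +1 means two-fold higher expression than
the control reference. The score is reported in log2 (delta-Ct) space;
``linear=True`` returns 2**HS instead. The gene identities of the
signature and controls are configuration (a panel), not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, get_logger

__all__ = ["ExpressionTable", "HypoxiaScoreResult", "read_ct_table", "read_panel",
           "normalise_expression", "hypoxia_score", "score_all_samples"]

log = get_logger(__name__)

CT_MAX = 45.0  # physical ceiling of a qPCR run
UNDETERMINED_IMPUTE_CT = 40.0


@dataclass
class ExpressionTable:
    """Ct values (genes x samples) with designated signature/control roles.

    ``undetermined_policy``: 'impute' replaces non-detected (NaN) signature
    Ct values with cycle 40; 'exclude' drops them from the median.
    """

    ct_values: pd.DataFrame
    signature_genes: list[str]
    control_genes: list[str]
    undetermined_policy: str = "impute"

    def __post_init__(self) -> None:
        overlap = set(self.signature_genes) & set(self.control_genes)
        if overlap:
            raise ConfigurationError(f"genes in both signature and controls: {overlap}")
        missing = (set(self.signature_genes) | set(self.control_genes)) \
            - set(self.ct_values.index)
        if missing:
            raise ConfigurationError(f"panel genes absent from Ct table: {sorted(missing)}")
        if self.undetermined_policy not in ("impute", "exclude"):
            raise ConfigurationError(
                f"unknown undetermined_policy {self.undetermined_policy!r}")
        vals = self.ct_values.loc[
            list(self.signature_genes) + list(self.control_genes)].to_numpy(float)
        bad = (vals <= 0) | (vals > CT_MAX)
        if np.any(bad & np.isfinite(vals)):
            raise ValueError(f"Ct values outside (0, {CT_MAX}] and not undetermined")

    @property
    def samples(self) -> list[str]:
        return list(self.ct_values.columns)


@dataclass
class HypoxiaScoreResult:
    score: float
    n_genes_used: int
    per_gene_delta: pd.Series = field(repr=False)


def read_panel(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a gene panel YAML with ``signature_genes`` and ``control_genes``."""
    with open(path) as fh:
        panel = yaml.safe_load(fh)
    try:
        return list(panel["signature_genes"]), list(panel["control_genes"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"panel {path} must define signature_genes "
                                 f"and control_genes") from exc


def read_ct_table(path: str | Path, signature_genes: list[str],
                  control_genes: list[str],
                  undetermined_policy: str = "impute") -> ExpressionTable:
    """Load a wide (gene rows x sample columns) or long CSV/TSV of Ct values.

    Long format needs columns ``gene``, ``sample``, ``ct``. The strings
    'Undetermined'/'NA' (any case) and empty cells become NaN.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols_lower = [c.lower() for c in df.columns]
    if {"gene", "sample", "ct"} <= set(cols_lower):
        df.columns = cols_lower
        wide = df.pivot(index="gene", columns="sample", values="ct")
    else:
        wide = df.set_index(df.columns[0])
    wide = wide.apply(pd.to_numeric, errors="coerce")
    return ExpressionTable(wide, signature_genes, control_genes, undetermined_policy)


def normalise_expression(table: ExpressionTable) -> pd.DataFrame:
    """Control-normalised log2 expression per signature gene and sample.

    Samples with any missing control gene are dropped with a warning.
    Undetermined signature Ct values are imputed to cycle 40 or left NaN
    (excluded downstream) per the table's policy.
    """
    controls = table.ct_values.loc[table.control_genes]
    usable = controls.notna().all(axis=0)
    dropped = [s for s, ok in usable.items() if not ok]
    if dropped:
        log.warning("samples skipped (missing control gene): %s", dropped)
    ref = controls.loc[:, usable].mean(axis=0)  # log2-geometric-mean reference
    sig = table.ct_values.loc[table.signature_genes, usable[usable].index].copy()
    if table.undetermined_policy == "impute":
        sig = sig.fillna(UNDETERMINED_IMPUTE_CT)
    return -(sig - ref)


def hypoxia_score(table: ExpressionTable, sample: str,
                  min_genes: int | None = None, linear: bool = False
                  ) -> HypoxiaScoreResult:
    """Hypoxia score of one sample: median control-normalised expression.

    ``min_genes`` defaults to half the signature size; a sample with fewer
    measured genes yields a NaN score flagged via ``n_genes_used``.
    """
    if sample not in table.samples:
        raise KeyError(f"sample {sample!r} not in table")
    delta_all = normalise_expression(table)
    if sample not in delta_all.columns:
        raise ValueError(f"sample {sample!r} skipped: missing control gene")
    delta = delta_all[sample].dropna()
    if min_genes is None:
        min_genes = max(1, len(table.signature_genes) // 2)
    if len(delta) < min_genes:
        log.warning("sample %s: only %d signature genes measured (< %d)",
                    sample, len(delta), min_genes)
        return HypoxiaScoreResult(float("nan"), int(len(delta)), delta)
    score = float(delta.median())
    if linear:
        score = float(2.0 ** score)
    return HypoxiaScoreResult(score, int(len(delta)), delta)


def score_all_samples(table: ExpressionTable, min_genes: int | None = None,
                      linear: bool = False) -> pd.Series:
    """Hypoxia score for every scoreable sample, as a named Series."""
    delta_all = normalise_expression(table)
    scores = {}
    for s in delta_all.columns:
        scores[s] = hypoxia_score(table, s, min_genes=min_genes, linear=linear).score
    return pd.Series(scores, name="hypoxia_score")
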