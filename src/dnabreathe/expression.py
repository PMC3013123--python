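"""Comparative-CT (delta-delta-Ct) qPCR arithmetic and pulse metadata.

Fold change between treated and control conditions is quantified on the
cycle-threshold scale: dCt_cond = mean Ct(gene, cond) - mean Ct(ref,
cond), ddCt = dCt_treated - dCt_control, fold = 2**(-ddCt).  Ideal
doubling per cycle is assumed (the comparative-CT convention); replicate
aggregation is the arithmetic mean on the Ct scale.  Genes are binned by
the strict two-fold rule: up if fold > 2, down if fold < 1/2, else
unchanged.

The irradiation-metadata helper checks pulse bookkeeping: peak power =
pulse energy / pulse width, average power = pulse energy x repetition
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default reference (housekeeping) gene for normalization.
DEFAULT_REFERENCE_GENE = "TBP"

CONDITIONS = ("treated", "control")


class CtTableError(ValueError):
    """Raised for incomplete or inconsistent Ct tables."""


@dataclass
class CtTable:
    """Long-format qPCR table: (gene, condition, replicate, ct)."""

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE

    REQUIRED = ("gene", "condition", "replicate", "ct")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise CtTableError(f"missing columns: {sorted(missing)}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise CtTableError(
                f"unknown conditions {sorted(bad_cond)}; expected "
                f"{CONDITIONS}"
            )
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise CtTableError("non-finite Ct values")
        if np.any((ct < 5) | (ct > 40)):
            warnings.warn(
                "Ct values outside the typical 5-40 cycle range",
                stacklevel=2,
            )
        for cond in CONDITIONS:
            sub = self.data[self.data["condition"] == cond]
            if self.reference_gene not in set(sub["gene"]):
                raise CtTableError(
                    f"reference gene {self.reference_gene!r} absent from "
                    f"condition {cond!r}"
                )

    @property
    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]

    def mean_ct(self, gene: str, condition: str) -> float:
        sub = self.data[
            (self.data["gene"] == gene) & (self.data["condition"] == condition)
        ]
        if sub.empty:
            raise CtTableError(
                f"no Ct rows for gene {gene!r} in condition {condition!r}"
            )
        return float(sub["ct"].mean())

    @classmethod
    def from_csv(cls, path, reference_gene: str = DEFAULT_REFERENCE_GENE,
                 sep: str = ","):
        return cls(pd.read_csv(path, sep=sep), reference_gene)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class FoldChangeRecord:
    """Gene-level comparative-CT result."""

    gene: str
    ddct: float
    fold: float
    regulation_class: str


def classify_regulation(fold: float, threshold: float = 2.0) -> str:
    """Strict two-fold rule: 'up' iff fold > threshold, 'down' iff
    fold < 1/threshold, else 'unchanged' (fold exactly 2 is unchanged)."""
    if not fold > 0:
        raise ValueError("fold must be > 0")
    if not threshold > 1:
        raise ValueError("threshold must be > 1")
    if fold > threshold:
        return "up"
    if fold < 1.0 / threshold:
        return "down"
    return "unchanged"


def ddct_fold_change(
    table: CtTable, gene: str, class_threshold: float = 2.0
) -> FoldChangeRecord:
    """Comparative-CT fold change of ``gene`` vs the table's reference."""
    ref = table.reference_gene
    dct = {}
    for cond in CONDITIONS:
        dct[cond] = table.mean_ct(gene, cond) - table.mean_ct(ref, cond)
    ddct = dct["treated"] - dct["control"]
    fold = float(2.0 ** (-ddct))
    return FoldChangeRecord(
        gene=gene,
        ddct=float(ddct),
        fold=fold,
        regulation_class=classify_regulation(fold, class_threshold),
    )


def fold_change_report(
    table: CtTable, class_threshold: float = 2.0
) -> pd.DataFrame:
    """Fold-change records for every non-reference gene, as a DataFrame."""
    recs = [ddct_fold_change(table, g, class_threshold) for g in table.genes]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in recs],
            "ddct": [r.ddct for r in recs],
            "fold": [r.fold for r in recs],
            "regulation_class": [r.regulation_class for r in recs],
        }
    )


def summarize_fractions(records) -> dict:
    """Fraction of genes per regulation class; fractions sum to 1."""
    classes = [
        r.regulation_class if isinstance(r, FoldChangeRecord) else str(r)
        for r in records
    ]
    if not classes:
        raise ValueError("no records to summarize")
    n = len(classes)
    return {
        "up": classes.count("up") / n,
        "down": classes.count("down") / n,
        "unchanged": classes.count("unchanged") / n,
    }


@dataclass(frozen=True)
class IrradiationMetadata:
    """Pulsed-source bookkeeping (SI units)."""

    pulse_energy_j: float = 1e-6
    pulse_width_s: float = 35e-15
    repetition_rate_hz: float = 1e3
    avg_power_density_w_cm2: float = 1e-3
    center_frequency_hz: float = 10e12

    def __post_init__(self):
        for name in (
            "pulse_energy_j", "pulse_width_s", "repetition_rate_hz",
            "avg_power_density_w_cm2", "center_frequency_hz",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def pulse_peak_power(meta: IrradiationMetadata) -> dict:
    """Peak and duty-cycle-averaged power of the pulse train (W)."""
    return {
        "peak_power_w": meta.pulse_energy_j / meta.pulse_width_s,
        "average_power_w": meta.pulse_energy_j * meta.repetition_rate_hz,
    }
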