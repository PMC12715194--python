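"""Hydroxyl-radical-footprinting quantification.

Turns a long-format table of DIA-quantified peptide intensities
(oxidized and unmodified forms across treatment conditions, temperatures
and replicates) into residue-level exposure calls.

The quantities, in order of construction:

* oxidation efficiency of a peptide,
  ``Oxi% = I_oxi / (I_oxi + I_naked)``;
* relative oxidation, the oxidized-treatment efficiency over the summed
  control efficiencies, ``Relative Oxi% = Oxi%_O / (Oxi%_C + Oxi%_F)``
  where C is the untreated control and F the Fe(II)-EDTA-only control;
* fold change between the cold and warm measurements,
  ``FC = Relative Oxi%(4C) / Relative Oxi%(30C)``.

A residue whose FC exceeds 1.20 is called more exposed at 4 C, below
0.83 more buried, otherwise unchanged; both thresholds are strict
inequalities and configurable.  Only peptides carrying at most a single
oxidized residue contribute, so every oxidized intensity can be
attributed to one site without localisation scoring.

Expected table schema (TSV with header, one row per measured form):

    peptide_sequence  protein_position  oxidized_residue
    n_oxidations_on_peptide  condition  temperature_C  replicate  intensity

``oxidized_residue`` is the 1-based position on the protein and is empty
for the unmodified form; ``condition`` is one of C/F/O; ``temperature_C``
is 4 or 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedControlError, UndefinedSignalError

logger = logging.getLogger(__name__)

CONDITIONS = ("C", "F", "O")
DEFAULT_UPPER = 1.20
DEFAULT_LOWER = 0.83

TABLE_COLUMNS = [
    "peptide_sequence", "protein_position", "oxidized_residue",
    "n_oxidations_on_peptide", "condition", "temperature_C",
    "replicate", "intensity",
]


@dataclass
class ResidueFoldChange:
    """Residue-level fold change with replicate statistics and a call."""

    residue: int
    amino_acid: str
    relative_oxi_4C: float
    relative_oxi_30C: float
    fc_mean: float
    fc_sem: float | None
    n_detections: int
    call: str


def oxidation_level(intensity_oxi: float, intensity_naked: float) -> float:
    """Oxi% = I_oxi / (I_oxi + I_naked), in [0, 1]."""
    if intensity_oxi < 0 or intensity_naked < 0:
        raise ValueError("intensities must be nonnegative")
    total = intensity_oxi + intensity_naked
    if total == 0:
        raise UndefinedSignalError("both oxidized and unmodified intensities are zero")
    return intensity_oxi / total


def relative_oxidation(oxi_O: float, oxi_C: float, oxi_F: float) -> float:
    """Relative Oxi% = Oxi%_O / (Oxi%_C + Oxi%_F)."""
    denom = oxi_C + oxi_F
    if denom <= 0:
        raise UndefinedControlError("control oxidation levels sum to zero")
    if oxi_O < 0:
        raise ValueError("oxidation levels must be nonnegative")
    return oxi_O / denom


def fold_change(rel_4C: float, rel_30C: float) -> float:
    """FC = Relative Oxi%(4C) / Relative Oxi%(30C)."""
    if rel_30C <= 0:
        raise UndefinedControlError("relative oxidation at 30C must be positive")
    if rel_4C < 0:
        raise ValueError("relative oxidation must be nonnegative")
    return rel_4C / rel_30C


def call_exposure_change(fc: float, upper: float = DEFAULT_UPPER,
                         lower: float = DEFAULT_LOWER) -> str:
    """Classify an FC as more_exposed / more_buried / unchanged.

    Strict inequalities: values exactly at a threshold are 'unchanged'.
    """
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if not (0 < lower < upper):
        raise ValueError(f"thresholds must satisfy 0 < lower < upper, got "
                         f"({lower}, {upper})")
    if fc > upper:
        return "more_exposed"
    if fc < lower:
        return "more_buried"
    return "unchanged"


def _validated(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table is missing columns: {missing}")
    bad_cond = set(table["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected C/F/O")
    if (table["intensity"] < 0).any():
        raise ValueError("intensities must be nonnegative")
    return table


def filter_single_oxidation(table: pd.DataFrame) -> pd.DataFrame:
    """Keep unmodified records and records with exactly one oxidation.

    Peptides observed with two or more oxidations are dropped (their site
    attribution is ambiguous); their unmodified partners are retained
    because they still serve as the denominator for singly-oxidized forms
    of the same peptide.
    """
    _validated(table)
    n_ox = table["n_oxidations_on_peptide"].astype(int)
    keep = (n_ox == 0) | ((n_ox == 1) & table["oxidized_residue"].notna())
    return table.loc[keep].copy()


def _amino_acid_lookup(oxidized: pd.DataFrame) -> dict[int, str]:
    """Map residue position -> one-letter code, read off the peptide itself."""
    out: dict[int, str] = {}
    for _, row in oxidized.iterrows():
        r = int(row["oxidized_residue"])
        if r in out:
            continue
        offset = r - int(row["protein_position"])
        seq = row["peptide_sequence"]
        if 0 <= offset < len(seq):
            out[r] = seq[offset]
        else:
            out[r] = "X"
    return out


def residue_fc_table(table: pd.DataFrame, upper: float = DEFAULT_UPPER,
                     lower: float = DEFAULT_LOWER,
                     aggregate: str = "replicate") -> pd.DataFrame:
    """Residue-level FC report from a peptide intensity table.

    ``aggregate='replicate'`` (default) computes one FC per replicate and
    reports mean +/- s.e.m.; ``aggregate='pooled'`` sums intensities over
    replicates first and reports a single FC.  Residues lacking
    control-condition coverage at either temperature are excluded with a
    logged warning and listed in ``result.attrs['excluded_residues']``.

    The output is sorted by residue and is invariant to the row order of
    the input.
    """
    if aggregate not in ("replicate", "pooled"):
        raise ValueError("aggregate must be 'replicate' or 'pooled'")
    work = filter_single_oxidation(table)
    n_ox = work["n_oxidations_on_peptide"].astype(int)
    oxi = work.loc[n_ox == 1].copy()
    naked = work.loc[n_ox == 0].copy()
    if oxi.empty:
        raise ValueError("no singly-oxidized records in the table")
    oxi["oxidized_residue"] = oxi["oxidized_residue"].astype(int)
    aa = _amino_acid_lookup(oxi)

    rep_cols = ["condition", "temperature_C"] + (
        ["replicate"] if aggregate == "replicate" else [])
    pep_key = ["peptide_sequence", "protein_position"] + rep_cols

    oxi_sum = (oxi.groupby(pep_key + ["oxidized_residue"], as_index=False)
               ["intensity"].sum().rename(columns={"intensity": "i_oxi"}))
    naked_sum = (naked.groupby(pep_key, as_index=False)["intensity"].sum()
                 .rename(columns={"intensity": "i_naked"}))
    merged = oxi_sum.merge(naked_sum, on=pep_key, how="left")
    merged["i_naked"] = merged["i_naked"].fillna(0.0)

    # residue-level: sum intensities over all covering peptides, then ratio
    res_key = ["oxidized_residue"] + rep_cols
    per_res = merged.groupby(res_key, as_index=False)[["i_oxi", "i_naked"]].sum()
    total = per_res["i_oxi"] + per_res["i_naked"]
    per_res = per_res.loc[total > 0].copy()
    per_res["oxi_pct"] = per_res["i_oxi"] / (per_res["i_oxi"] + per_res["i_naked"])

    idx_cols = ["oxidized_residue"] + (["replicate"] if aggregate == "replicate" else [])
    wide = per_res.pivot_table(index=idx_cols, columns=["condition", "temperature_C"],
                               values="oxi_pct", aggfunc="first")

    records = []
    excluded: list[int] = []
    for residue, grp in wide.groupby(level="oxidized_residue"):
        rels = {4: [], 30: []}
        fcs = []
        for _, row in grp.iterrows():
            rel_t = {}
            for t in (4, 30):
                o = row.get(("O", t), np.nan)
                c = row.get(("C", t), np.nan)
                f = row.get(("F", t), np.nan)
                if np.isnan(o) or np.isnan(c) or np.isnan(f) or (c + f) <= 0:
                    continue
                rel_t[t] = relative_oxidation(o, c, f)
            if 4 in rel_t and 30 in rel_t and rel_t[30] > 0:
                fcs.append(fold_change(rel_t[4], rel_t[30]))
                rels[4].append(rel_t[4])
                rels[30].append(rel_t[30])
        if not fcs:
            excluded.append(int(residue))
            continue
        fcs = np.asarray(fcs, dtype=float)
        fc_mean = float(fcs.mean())
        fc_sem = float(fcs.std(ddof=1) / np.sqrt(fcs.size)) if fcs.size >= 2 else np.nan
        records.append({
            "residue": int(residue),
            "amino_acid": aa.get(int(residue), "X"),
            "relative_oxi_4C": float(np.mean(rels[4])),
            "relative_oxi_30C": float(np.mean(rels[30])),
            "fc_mean": fc_mean,
            "fc_sem": fc_sem,
            "n_detections": int(fcs.size),
            "call": call_exposure_change(fc_mean, upper=upper, lower=lower),
        })
    if excluded:
        logger.warning("residue_fc_table: excluded %d residue(s) without "
                       "control coverage: %s", len(excluded), sorted(excluded))
    out = pd.DataFrame.from_records(records).sort_values("residue").reset_index(drop=True)
    out.attrs["excluded_residues"] = sorted(excluded)
    out.attrs["thresholds"] = (upper, lower)
    return out


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide intensity table (TSV, UTF-8, dot decimal)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide_sequence": str,
                                            "condition": str})
    df["oxidized_residue"] = df["oxidized_residue"].astype("Int64")
    return _validated(df)


def write_peptide_table(table: pd.DataFrame, path) -> None:
    _validated(table).to_csv(path, sep="\t", index=False)


def write_residue_report(report: pd.DataFrame, path) -> None:
    """Write the residue FC report TSV (full precision)."""
    report.to_csv(path, sep="\t", index=False)
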