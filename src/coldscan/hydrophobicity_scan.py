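"""Side-chain-hydrophobicity scan of gating thermodynamics.

At each candidate temperature-sensing site the channel is mutated to
residues of varying side-chain hydrophobicity (SCH), the gating enthalpy
dH of each functional mutant is measured, and the dependence is
summarised by the slope of an ordinary least-squares fit of dH against
the SCH value of the residue at that site ("slope factor").

Under the water-protein-interaction picture of cold sensing, a site that
becomes *more exposed* on cooling should show more negative dH as the
side chain becomes more hydrophobic.  With the transfer-free-energy
convention used by the built-in scales (hydrophobic residues carry lower
values), that is a *positive* slope factor; a site that becomes more
buried should show a negative one.  Plotting FC against slope factor,
consistent sites therefore fall in the first (FC>1, slope>0) and third
(FC<1, slope<0) quadrants, and the aggregate statistic is the fraction
of sites in those quadrants among sites whose |slope| exceeds a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, UndefinedResultError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named amino-acid -> transfer-free-energy (kcal/mol) map."""

    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale '{self.name}' is missing residues "
                             f"{sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa.upper()]

    @classmethod
    def from_name(cls, name: str) -> "HydrophobicityScale":
        """Load a built-in scale ('hessa' or 'moon_fleming')."""
        fname = {"hessa": "hessa.tsv", "moon_fleming": "moon_fleming.tsv"}.get(name)
        if fname is None:
            raise ValueError(f"unknown scale '{name}'; "
                             "use 'hessa', 'moon_fleming' or from_tsv()")
        with resources.files("coldscan.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        return cls(name=name, values=dict(zip(df["amino_acid"], df["value"])))

    @classmethod
    def from_tsv(cls, path, name: str = "custom") -> "HydrophobicityScale":
        """Load a custom scale from a two-column TSV (amino_acid, value)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(name=name, values=dict(zip(df["amino_acid"], df["value"])))


@dataclass
class MutantThermoRecord:
    """Gating thermodynamics of one residue identity at one site."""

    site: int
    residue: str
    dH: float                 # kcal/mol
    dS: float = float("nan")  # kcal/(mol.K)

    def __post_init__(self):
        if self.residue.upper() not in AMINO_ACIDS:
            raise ValueError(f"non-canonical residue '{self.residue}'")
        if not np.isfinite(self.dH):
            raise ValueError("dH must be finite")


@dataclass
class SiteSlope:
    """Slope factor of dH against SCH at one site."""

    site: int
    slope_factor: float  # kcal/mol dH per kcal/mol SCH (dimensionless)
    r_squared: float
    n_mutants: int
    fc: float | None = None  # footprinting fold change, when available


@dataclass
class ConsistencyResult:
    """Quadrant classes and consistency proportions over a site set."""

    scale_name: str
    classes: dict[int, str]               # site -> quadrant class
    proportions: dict[float, float]       # |slope| threshold -> fraction
    n_indeterminate: int
    n_sites: dict[float, int]             # threshold -> sites entering the fraction


def slope_factor(records: list[MutantThermoRecord],
                 scale: HydrophobicityScale,
                 fc: float | None = None) -> SiteSlope:
    """OLS slope of dH against the site's SCH values across mutants."""
    if len(records) < 2:
        raise DegenerateFitError("slope factor needs >=2 mutants at the site")
    sites = {r.site for r in records}
    if len(sites) != 1:
        raise ValueError(f"records span multiple sites: {sorted(sites)}")
    x = np.array([scale[r.residue] for r in records], dtype=float)
    y = np.array([r.dH for r in records], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateFitError("all mutants share one hydrophobicity value")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SiteSlope(site=records[0].site, slope_factor=float(slope),
                     r_squared=r2, n_mutants=len(records), fc=fc)


def classify_consistency(fc: float, slope: float) -> str:
    """Quadrant class of a (FC, slope factor) pair.

    Consistent: first quadrant (fc>1, slope>0) or third (fc<1, slope<0).
    fc exactly 1 or slope exactly 0 is indeterminate and reported apart.
    """
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if fc == 1.0 or slope == 0.0:
        return INDETERMINATE
    if (fc > 1.0) == (slope > 0.0):
        return CONSISTENT
    return INCONSISTENT


def consistency_proportion(sites: list[SiteSlope], slope_threshold: float = 0.0,
                           signed: bool = False) -> tuple[float, int]:
    """Fraction of hypothesis-consistent sites above a slope threshold.

    Sites with ``|slope_factor| > slope_threshold`` (or
    ``slope_factor > slope_threshold`` in ``signed`` mode) and a
    determinate quadrant class enter the fraction.  Returns
    ``(proportion, n_sites)``; an empty filtered set raises
    :class:`UndefinedResultError`.
    """
    selected = []
    for s in sites:
        if s.fc is None:
            continue
        mag = s.slope_factor if signed else abs(s.slope_factor)
        if mag > slope_threshold:
            cls = classify_consistency(s.fc, s.slope_factor)
            if cls != INDETERMINATE:
                selected.append(cls)
    if not selected:
        raise UndefinedResultError(
            f"no determinate sites with |slope| > {slope_threshold}")
    frac = sum(c == CONSISTENT for c in selected) / len(selected)
    return frac, len(selected)


def consistency_result(sites: list[SiteSlope], scale: HydrophobicityScale,
                       thresholds: tuple[float, ...] = (0.0, 5.0, 10.0),
                       signed: bool = False) -> ConsistencyResult:
    """Quadrant classes plus proportions at several slope thresholds."""
    classes = {s.site: classify_consistency(s.fc, s.slope_factor)
               for s in sites if s.fc is not None}
    n_ind = sum(c == INDETERMINATE for c in classes.values())
    props: dict[float, float] = {}
    counts: dict[float, int] = {}
    for th in thresholds:
        try:
            frac, n = consistency_proportion(sites, th, signed=signed)
        except UndefinedResultError:
            frac, n = float("nan"), 0
        props[th] = frac
        counts[th] = n
    return ConsistencyResult(scale_name=scale.name, classes=classes,
                             proportions=props, n_indeterminate=n_ind,
                             n_sites=counts)


def read_mutant_table(path) -> dict[int, list[MutantThermoRecord]]:
    """Read a mutant thermodynamics TSV (site, residue, dH[, dS])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[int, list[MutantThermoRecord]] = {}
    for _, row in df.iterrows():
        rec = MutantThermoRecord(site=int(row["site"]), residue=str(row["residue"]),
                                 dH=float(row["dH"]),
                                 dS=float(row.get("dS", float("nan"))))
        out.setdefault(rec.site, []).append(rec)
    return out
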