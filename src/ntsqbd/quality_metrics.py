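"""Material and process quality attributes for notoginseng total saponins.

A *Panax notoginseng* lot is characterised by what a standardized 80 %-ethanol
reflux extraction can recover from it: the extractable content of five
saponins (notoginsenoside R1 and ginsenosides Rg1, Re, Rb1, Rd) and the
extractable dry matter, all in mg per g of raw material.  The manufacturing
run that follows (extraction, concentration, water precipitation, resin
chromatography) is judged on its chromatography eluate: per-saponin purities,
total saponin purity, dry-matter yield and total saponin yield.

Unit conventions used throughout the package:

* masses in g;
* dry-matter concentrations as mass fractions (g/g);
* saponin concentrations in mg/g;
* extractable contents and yields in mg per g *Panax notoginseng*;
* purities as dimensionless fractions internally, rendered as percent only
  at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._exceptions import DomainError

#: Monitored saponins, in index order 1..5.
SAPONINS = (
    "notoginsenoside R1",
    "ginsenoside Rg1",
    "ginsenoside Re",
    "ginsenoside Rb1",
    "ginsenoside Rd",
)

N_SAPONINS = len(SAPONINS)

# Relative tolerance when checking that the saponins cannot outweigh the dry
# matter that contains them; printed 3-sf inputs would otherwise trip it.
_MASS_BALANCE_RTOL = 1e-9


def _check_concentrations(dry_matter_conc: float, saponin_conc: Sequence[float],
                          what: str) -> None:
    if not 0.0 <= dry_matter_conc <= 1.0:
        raise DomainError(f"{what}: dry matter concentration must be a mass "
                          f"fraction in [0, 1], got {dry_matter_conc}")
    if len(saponin_conc) != N_SAPONINS:
        raise DomainError(f"{what}: expected {N_SAPONINS} saponin "
                          f"concentrations, got {len(saponin_conc)}")
    if any(c < 0 for c in saponin_conc):
        raise DomainError(f"{what}: saponin concentrations must be >= 0")
    # saponins are part of the dry matter: sum (as g/g) cannot exceed it
    total = sum(saponin_conc) / 1000.0
    if total > dry_matter_conc * (1 + _MASS_BALANCE_RTOL) + 1e-15:
        raise DomainError(
            f"{what}: saponins ({total:.4g} g/g) exceed dry matter "
            f"({dry_matter_conc:.4g} g/g)")


@dataclass(frozen=True)
class ExtractionRecord:
    """Pooled analytical record of the two characterisation extractions.

    The two reflux extracts are filtered and combined before analysis, so a
    single record holds the pooled extract mass and concentrations.
    """

    material_mass: float            # g Panax notoginseng (M_PN)
    extract_mass: float             # g combined extract (M_EX)
    extract_dry_matter_conc: float  # g/g (DM_EX)
    extract_saponin_conc: tuple[float, ...]  # mg/g, index order SAPONINS

    def __post_init__(self):
        if self.material_mass <= 0:
            raise DomainError("material_mass must be > 0")
        if self.extract_mass <= 0:
            raise DomainError("extract_mass must be > 0")
        object.__setattr__(self, "extract_saponin_conc",
                           tuple(float(c) for c in self.extract_saponin_conc))
        _check_concentrations(self.extract_dry_matter_conc,
                              self.extract_saponin_conc, "ExtractionRecord")


@dataclass(frozen=True)
class EluateRecord:
    """Analytical record of one run's chromatography eluate."""

    material_mass: float           # g Panax notoginseng (M_PN)
    eluate_mass: float             # g eluate (M_EL)
    eluate_dry_matter_conc: float  # g/g (DMC_EL)
    eluate_saponin_conc: tuple[float, ...]  # mg/g (C_EL,i)

    def __post_init__(self):
        if self.material_mass <= 0:
            raise DomainError("material_mass must be > 0")
        if self.eluate_mass <= 0:
            raise DomainError("eluate_mass must be > 0")
        object.__setattr__(self, "eluate_saponin_conc",
                           tuple(float(c) for c in self.eluate_saponin_conc))
        _check_concentrations(self.eluate_dry_matter_conc,
                              self.eluate_saponin_conc, "EluateRecord")


@dataclass(frozen=True)
class MaterialBatch:
    """One lot of *Panax notoginseng* and its extractable quality attributes.

    ``z`` holds (Z1..Z5, Z6): the five extractable saponin contents and the
    extractable dry matter content, all in mg/g.
    """

    batch_id: str
    z: tuple[float, float, float, float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "z", tuple(float(v) for v in self.z))
        if len(self.z) != 6:
            raise DomainError("MaterialBatch needs exactly 6 attributes Z1..Z6")
        if any(v < 0 for v in self.z):
            raise DomainError(f"{self.batch_id}: Z values must be >= 0")
        if sum(self.z[:5]) > self.z[5] * (1 + _MASS_BALANCE_RTOL) + 1e-12:
            raise DomainError(
                f"{self.batch_id}: saponin contents sum to {sum(self.z[:5]):.4g}"
                f" mg/g > extractable dry matter {self.z[5]:.4g} mg/g")

    def as_dict(self) -> dict[str, float]:
        return {f"Z{k + 1}": v for k, v in enumerate(self.z)}


@dataclass(frozen=True)
class EluateQuality:
    """Process quality attributes computed from one eluate record.

    ``sp`` are per-saponin purities as fractions; ``tsp`` their sum; ``tsc``
    the total saponin concentration of the eluate (mg/g); ``tsy`` and ``dmy``
    the total-saponin and dry-matter yields in mg per g raw material.
    """

    sp: tuple[float, float, float, float, float]
    tsp: float
    tsc: float
    tsy: float
    dmy: float


def extractable_dry_matter(rec: ExtractionRecord) -> float:
    """Extractable dry matter content of the raw material, mg/g.

    EDM = M_EX * DM_EX / M_PN, converted from g/g to mg/g.
    """
    return rec.extract_mass * rec.extract_dry_matter_conc / rec.material_mass * 1000.0


def extractable_saponin_content(rec: ExtractionRecord, i: int) -> float:
    """Extractable content of saponin ``i`` (1-based, order ``SAPONINS``), mg/g."""
    if not 1 <= i <= N_SAPONINS:
        raise DomainError(f"saponin index must be in 1..{N_SAPONINS}, got {i}")
    return rec.extract_mass * rec.extract_saponin_conc[i - 1] / rec.material_mass


def material_batch_from_extraction(batch_id: str, rec: ExtractionRecord) -> MaterialBatch:
    """Characterise a lot: derive Z1..Z6 from its pooled extraction record."""
    z = tuple(extractable_saponin_content(rec, i) for i in range(1, N_SAPONINS + 1))
    return MaterialBatch(batch_id, z + (extractable_dry_matter(rec),))


def eluate_quality(rec: EluateRecord) -> EluateQuality:
    """Compute all process quality attributes of one eluate.

    TSC = sum_i C_EL,i ;  TSY = M_EL * TSC / M_PN ;  DMY = M_EL * DMC_EL / M_PN ;
    SP_i = C_EL,i / DM_EL ;  TSP = sum_i SP_i.  By construction
    TSY = TSP * DMY holds exactly.
    """
    tsc = sum(rec.eluate_saponin_conc)
    if rec.eluate_dry_matter_conc == 0.0:
        if tsc > 0:
            raise DomainError("eluate has saponins but zero dry matter")
        sp = (0.0,) * N_SAPONINS
    else:
        # mg/g over g/g: divide by 1000 to express the purity as a fraction
        sp = tuple(c / 1000.0 / rec.eluate_dry_matter_conc
                   for c in rec.eluate_saponin_conc)
    tsy = rec.eluate_mass * tsc / rec.material_mass
    dmy = rec.eluate_mass * rec.eluate_dry_matter_conc * 1000.0 / rec.material_mass
    return EluateQuality(sp=sp, tsp=sum(sp), tsc=tsc, tsy=tsy, dmy=dmy)


def pool(records: Iterable[ExtractionRecord]) -> ExtractionRecord:
    """Pool several extracts of the same material into one combined record.

    Concentrations are mass-weighted means; the material mass must agree
    across records (they are extracts of the same charge).
    """
    recs = list(records)
    if not recs:
        raise DomainError("cannot pool zero extraction records")
    m_pn = recs[0].material_mass
    if any(abs(r.material_mass - m_pn) > 1e-9 * m_pn for r in recs):
        raise DomainError("pooled records must share the same material mass")
    total = sum(r.extract_mass for r in recs)
    dm = sum(r.extract_mass * r.extract_dry_matter_conc for r in recs) / total
    sc = tuple(
        sum(r.extract_mass * r.extract_saponin_conc[i] for r in recs) / total
        for i in range(N_SAPONINS))
    return ExtractionRecord(material_mass=m_pn, extract_mass=total,
                            extract_dry_matter_conc=dm, extract_saponin_conc=sc)
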