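"""Core data types for SNP gene panels, nuclear pedigrees and genotypes.

The analysis operates on two-generation nuclear families (two founders plus
a sibship) genotyped at small per-gene SNP panels (one to six markers per
candidate gene).  Alleles are opaque symbols: no strand flipping or
reference/alt orientation is applied, and markers may be multi-allelic so
that fully informative loci can be constructed for analytic tests.

File formats
------------
* Pedigree files follow the pre-makeped LINKAGE dialect: whitespace-
  delimited, one individual per line::

      FAMILY_ID INDIVIDUAL_ID FATHER_ID MOTHER_ID SEX AFFECTION  a1 a2  a1 a2 ...

  with SEX coded 1=male/2=female/0=unknown, AFFECTION 2=affected/
  1=unaffected/0=unknown, two allele columns per marker in panel order and
  ``0`` for a missing allele.
* Panel files are TSV with columns ``gene``, ``marker_id``,
  ``index_in_gene``, ``alleles`` (comma-joined), ``freqs`` (comma-joined,
  optional), ``category`` and ``transcript_size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele (``0`` in PED files).
MISSING = "."

PED_MISSING = "0"

CATEGORIES = ("arRP", "LCA-specific")

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}
AFFECTION_CODES = {"2": "affected", "1": "unaffected", "0": "unknown"}
AFFECTION_TO_CODE = {v: k for k, v in AFFECTION_CODES.items()}


class PedParseError(ValueError):
    """Raised for malformed pedigree or panel files (carries a line number)."""


@dataclass(frozen=True)
class SnpMarker:
    """One SNP of a gene panel.

    Parameters
    ----------
    marker_id : str
        Identifier, typically an rsID; unique within its gene panel.
    gene : str
        Gene symbol the marker is anchored to.
    index_in_gene : int
        0-based ordinal within the panel.
    alleles : frozenset of str
        Allele symbols (at least two).
    allele_freqs : mapping, optional
        Population allele frequencies, used only by the simulator.  When
        present they must cover exactly the allele set and sum to one.
    """

    marker_id: str
    gene: str
    index_in_gene: int
    alleles: frozenset
    allele_freqs: Mapping[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "alleles", frozenset(self.alleles))
        if len(self.alleles) < 2:
            raise ValueError(f"marker {self.marker_id}: needs >=2 alleles")
        if MISSING in self.alleles or PED_MISSING in self.alleles:
            raise ValueError(
                f"marker {self.marker_id}: allele symbols may not use the "
                f"missing codes {MISSING!r}/{PED_MISSING!r}"
            )
        if self.allele_freqs is not None:
            freqs = dict(self.allele_freqs)
            if set(freqs) != set(self.alleles):
                raise ValueError(
                    f"marker {self.marker_id}: freqs must cover the allele set"
                )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"marker {self.marker_id}: allele freqs sum to {total}, not 1"
                )
            object.__setattr__(self, "allele_freqs", freqs)


@dataclass(frozen=True)
class GenePanel:
    """A candidate gene's ordered SNP panel (1–6 markers)."""

    gene: str
    markers: tuple
    category: str = "arRP"
    transcript_size: int = 1

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        if not 1 <= len(self.markers) <= 6:
            raise ValueError(f"panel {self.gene}: needs 1-6 markers, got {len(self.markers)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"panel {self.gene}: category must be one of {CATEGORIES}")
        if self.transcript_size <= 0:
            raise ValueError(f"panel {self.gene}: transcript_size must be positive")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"panel {self.gene}: duplicate marker ids")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> tuple:
        return tuple(m.marker_id for m in self.markers)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of allele calls at one marker.

    Either both alleles are present or both are :data:`MISSING`; half-calls
    are demoted to missing (with a logged warning) because no half-call rule
    exists for this assay model.
    """

    allele_a: str = MISSING
    allele_b: str = MISSING

    def __post_init__(self):
        a, b = self.allele_a, self.allele_b
        if (a == MISSING) != (b == MISSING):
            logger.warning("half-called genotype %s/%s demoted to missing", a, b)
            a = b = MISSING
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def is_missing(self) -> bool:
        return self.allele_a == MISSING

    @property
    def alleles(self) -> tuple:
        return (self.allele_a, self.allele_b)

    def __iter__(self):
        return iter(self.alleles)


MISSING_GENOTYPE = Genotype()


@dataclass
class Individual:
    """A pedigree member with per-marker genotype calls."""

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    genotypes: dict = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def genotype(self, marker_id: str) -> Genotype:
        return self.genotypes.get(marker_id, MISSING_GENOTYPE)

    def is_typed_at(self, panel: GenePanel) -> bool:
        """True if at least one marker of *panel* has a non-missing call."""
        return any(not self.genotype(mid).is_missing for mid in panel.marker_ids())

    def is_typed(self, panels: Iterable[GenePanel]) -> bool:
        return any(self.is_typed_at(p) for p in panels)


@dataclass
class NuclearFamily:
    """Two founders plus a sibship.

    An absent (ungenotyped and unsampled) parent is represented as ``None``;
    downstream phase enumeration then treats that parent's haplotypes as
    fully unconstrained.
    """

    family_id: str
    father: Individual | None
    mother: Individual | None
    children: list

    def __post_init__(self):
        if not self.children:
            raise ValueError(f"family {self.family_id}: needs >=1 child")

    @property
    def members(self) -> list:
        out = []
        if self.father is not None:
            out.append(self.father)
        if self.mother is not None:
            out.append(self.mother)
        out.extend(self.children)
        return out

    def affected_children(self) -> list:
        return [c for c in self.children if c.affection == "affected"]

    def unaffected_children(self) -> list:
        return [c for c in self.children if c.affection == "unaffected"]


# Haplotypes are plain tuples of allele symbols (or MISSING), one entry per
# panel marker, in panel order.

def haplotype_from_string(s: str) -> tuple:
    """Build a haplotype from a compact string like ``"CCTGCA"``.

    ``.`` (or ``0``) denotes a wildcard/missing position.
    """
    return tuple(MISSING if ch in (MISSING, PED_MISSING) else ch for ch in s)


@dataclass(frozen=True)
class ValidationFinding:
    """One validation problem found in a family (never an exception)."""

    family_id: str
    kind: str
    message: str

    def __str__(self):
        return f"[{self.family_id}] {self.kind}: {self.message}"


def validate_family(family: NuclearFamily, panels: Sequence[GenePanel]) -> list:
    """Check a family against the recessive-analysis contract.

    Returns a list of :class:`ValidationFinding` (empty for a well-formed
    family).  Checked: allele symbols belong to the marker's allele set;
    founders are not affected (pseudo-dominant segregation is not modelled);
    genotyped markers belong to some panel; children reference this family's
    founders.  Pure: never mutates its input.
    """
    findings = []
    marker_by_id = {m.marker_id: m for p in panels for m in p.markers}

    def add(kind, msg):
        findings.append(ValidationFinding(family.family_id, kind, msg))

    for person in family.members:
        for mid, g in person.genotypes.items():
            marker = marker_by_id.get(mid)
            if marker is None:
                add("orphan marker", f"{person.individual_id}: genotype at unknown marker {mid}")
                continue
            for allele in g.alleles:
                if allele != MISSING and allele not in marker.alleles:
                    add(
                        "unknown allele",
                        f"{person.individual_id} at {mid}: allele {allele!r} "
                        f"not in {sorted(marker.alleles)}",
                    )
    for role, parent in (("father", family.father), ("mother", family.mother)):
        if parent is not None and parent.affection == "affected":
            add(
                "affected founder unsupported",
                f"{role} {parent.individual_id} is affected; pseudo-dominant "
                "segregation is outside the recessive model",
            )
    father_id = family.father.individual_id if family.father is not None else None
    mother_id = family.mother.individual_id if family.mother is not None else None
    for child in family.children:
        if child.father_id is None or child.mother_id is None:
            add("missing parent link", f"child {child.individual_id} lacks a parent id")
            continue
        if father_id is not None and child.father_id != father_id:
            add(
                "absent parent reference",
                f"child {child.individual_id} names father {child.father_id}, "
                f"family founder is {father_id}",
            )
        if mother_id is not None and child.mother_id != mother_id:
            add(
                "absent parent reference",
                f"child {child.individual_id} names mother {child.mother_id}, "
                f"family founder is {mother_id}",
            )
    if not family.affected_children():
        add("no affected child", "cohort is ascertained through affected children")
    return findings


def validate_cohort(cohort: Sequence[NuclearFamily], panels: Sequence[GenePanel]) -> list:
    out = []
    for fam in cohort:
        out.extend(validate_family(fam, panels))
    return out


# ---------------------------------------------------------------------------
# Pedigree file I/O


def _panel_marker_order(panels: Sequence[GenePanel]) -> list:
    return [m.marker_id for p in panels for m in p.markers]


def read_ped(path, panels: Sequence[GenePanel]) -> list:
    """Read a LINKAGE-style pedigree file into nuclear families.

    Genotype column pairs follow the concatenated marker order of *panels*.
    Allele code ``0`` maps to missing.  Raises :class:`PedParseError` with a
    line number for malformed lines, duplicate individual ids, genotype
    column count mismatches, or children naming parents absent from their
    family's records.
    """
    marker_order = _panel_marker_order(panels)
    n_cols = 6 + 2 * len(marker_order)
    individuals: dict = {}
    fam_order: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != n_cols:
                raise PedParseError(
                    f"{path}:{lineno}: expected {n_cols} columns "
                    f"({len(marker_order)} markers), got {len(fields)}"
                )
            fam_id, ind_id, fa_id, mo_id, sex_c, aff_c = fields[:6]
            if (fam_id, ind_id) in individuals:
                raise PedParseError(f"{path}:{lineno}: duplicate individual {ind_id} in family {fam_id}")
            if sex_c not in SEX_CODES:
                raise PedParseError(f"{path}:{lineno}: bad sex code {sex_c!r}")
            if aff_c not in AFFECTION_CODES:
                raise PedParseError(f"{path}:{lineno}: bad affection code {aff_c!r}")
            genos = {}
            allele_cols = fields[6:]
            for i, mid in enumerate(marker_order):
                a = allele_cols[2 * i]
                b = allele_cols[2 * i + 1]
                a = MISSING if a == PED_MISSING else a
                b = MISSING if b == PED_MISSING else b
                g = Genotype(a, b)
                if not g.is_missing:
                    genos[mid] = g
            person = Individual(
                individual_id=ind_id,
                family_id=fam_id,
                father_id=None if fa_id == "0" else fa_id,
                mother_id=None if mo_id == "0" else mo_id,
                sex=SEX_CODES[sex_c],
                affection=AFFECTION_CODES[aff_c],
                genotypes=genos,
            )
            individuals[(fam_id, ind_id)] = person
            if fam_id not in fam_order:
                fam_order.append(fam_id)

    families = []
    for fam_id in fam_order:
        members = [p for (f, _), p in individuals.items() if f == fam_id]
        founders = {p.individual_id: p for p in members if p.is_founder}
        children = [p for p in members if not p.is_founder]
        if not children:
            raise PedParseError(f"{path}: family {fam_id} has no children")
        father_ids = {c.father_id for c in children}
        mother_ids = {c.mother_id for c in children}
        if len(father_ids) != 1 or len(mother_ids) != 1:
            raise PedParseError(
                f"{path}: family {fam_id} is not a single nuclear unit "
                f"(fathers {sorted(father_ids)}, mothers {sorted(mother_ids)})"
            )
        fa_id = father_ids.pop()
        mo_id = mother_ids.pop()
        for pid, role in ((fa_id, "father"), (mo_id, "mother")):
            if pid is not None and pid not in founders:
                raise PedParseError(
                    f"{path}: family {fam_id}: children name {role} {pid!r} "
                    "who is not a founder record in this family"
                )
        father = founders.get(fa_id) if fa_id is not None else None
        mother = founders.get(mo_id) if mo_id is not None else None
        # A founder placeholder with all-missing genotypes stands for an
        # unsampled parent; keep the record (its id anchors the children).
        families.append(NuclearFamily(fam_id, father, mother, children))
    return families


def write_ped(cohort: Sequence[NuclearFamily], panels: Sequence[GenePanel], path) -> None:
    """Write families back to the LINKAGE-style dialect read by :func:`read_ped`."""
    marker_order = _panel_marker_order(panels)
    lines = []
    for fam in cohort:
        for person in fam.members:
            cols = [
                fam.family_id,
                person.individual_id,
                person.father_id or "0",
                person.mother_id or "0",
                SEX_TO_CODE[person.sex],
                AFFECTION_TO_CODE[person.affection],
            ]
            for mid in marker_order:
                g = person.genotype(mid)
                cols.append(PED_MISSING if g.allele_a == MISSING else g.allele_a)
                cols.append(PED_MISSING if g.allele_b == MISSING else g.allele_b)
            lines.append(" ".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panel file I/O


def read_panel(path) -> list:
    """Read a gene-panel TSV into :class:`GenePanel` objects (file order)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "marker_id", "index_in_gene", "alleles", "category", "transcript_size"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise PedParseError(f"{path}: panel file missing columns {sorted(missing_cols)}")
    panels = []
    for gene, grp in df.groupby("gene", sort=False):
        if grp["marker_id"].duplicated().any():
            dup = grp["marker_id"][grp["marker_id"].duplicated()].iloc[0]
            raise PedParseError(f"{path}: duplicate marker {dup!r} in gene {gene}")
        grp = grp.sort_values("index_in_gene", key=lambda s: s.astype(int))
        markers = []
        for _, row in grp.iterrows():
            alleles = tuple(row["alleles"].split(","))
            freqs = None
            if "freqs" in df.columns and isinstance(row.get("freqs"), str) and row["freqs"]:
                vals = [float(x) for x in row["freqs"].split(",")]
                if len(vals) != len(alleles):
                    raise PedParseError(
                        f"{path}: gene {gene} marker {row['marker_id']}: "
                        f"{len(vals)} freqs for {len(alleles)} alleles"
                    )
                freqs = dict(zip(alleles, vals))
            markers.append(
                SnpMarker(
                    marker_id=row["marker_id"],
                    gene=gene,
                    index_in_gene=int(row["index_in_gene"]),
                    alleles=frozenset(alleles),
                    allele_freqs=freqs,
                )
            )
        if len(markers) > 6:
            raise PedParseError(f"{path}: gene {gene} has {len(markers)} markers (max 6)")
        cat = grp["category"].iloc[0]
        size = int(grp["transcript_size"].iloc[0])
        try:
            panels.append(GenePanel(gene, tuple(markers), category=cat, transcript_size=size))
        except ValueError as exc:
            raise PedParseError(f"{path}: gene {gene}: {exc}") from exc
    return panels


def write_panel(panels: Sequence[GenePanel], path) -> None:
    rows = []
    for p in panels:
        for m in p.markers:
            alleles = sorted(m.alleles)
            rows.append(
                {
                    "gene": p.gene,
                    "marker_id": m.marker_id,
                    "index_in_gene": m.index_in_gene,
                    "alleles": ",".join(alleles),
                    "freqs": ",".join(repr(float(m.allele_freqs[a])) for a in alleles)
                    if m.allele_freqs
                    else "",
                    "category": p.category,
                    "transcript_size": p.transcript_size,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
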