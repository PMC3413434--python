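"""Gene-drop simulator for ascertained recessive nuclear-family cohorts.

Cohorts are generated under the model the analysis assumes: per gene, each
founder receives two haplotypes sampled marker-by-marker from population
allele frequencies (linkage equilibrium among a panel's SNPs by default —
panel SNPs are chosen from different haplotype blocks, so independence is
the neutral default); one maternal and one paternal founder copy at a
designated causal gene are "risk" copies; each child independently inherits
one copy per parent per gene; a child is affected iff it inherits both risk
copies (subject to penetrance) or is a phenocopy.  Families are
rejection-sampled on the sibship's affection pattern until the configured
numbers of affected and unaffected genotyped sibs are available, since real
cohorts condition on observed family structure.

False paternity is simulated by drawing an unrelated latent father whose
haplotypes the children actually inherit, while the recorded father keeps
his own genotypes.  Genotype error (symmetric substitution to a uniformly
chosen other allele) and missingness are applied last, to observed calls
only; the truth record keeps all latent state.

Everything is reproducible from one master seed; per-family substreams are
derived deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pedigree import (
    MISSING,
    GenePanel,
    Genotype,
    Individual,
    NuclearFamily,
    SnpMarker,
    write_panel,
    write_ped,
)

# 28 candidate genes for arRP / LCA with panel sizes and synthetic stand-in
# transcript sizes (bp, order of magnitude of the real coding sequences).
# The four genes whose assays dropped out carry 5 SNPs instead of 6.
_GENE_TABLE = [
    # (gene, n_snps, category, transcript_size)
    ("ABCA4", 6, "arRP", 6822),
    ("AIPL1", 6, "LCA-specific", 1155),
    ("CEP290", 6, "LCA-specific", 7440),
    ("CERKL", 6, "arRP", 1597),
    ("CNGA1", 6, "arRP", 2082),
    ("CNGB1", 6, "arRP", 3723),
    ("CRB1", 6, "arRP", 4218),
    ("CRX", 6, "LCA-specific", 900),
    ("GUCY2D", 6, "LCA-specific", 3312),
    ("LCA5", 6, "LCA-specific", 2094),
    ("LRAT", 5, "arRP", 693),
    ("MERTK", 6, "arRP", 3000),
    ("NR2E3", 6, "arRP", 1233),
    ("NRL", 6, "arRP", 714),
    ("PDE6A", 6, "arRP", 2583),
    ("PDE6B", 6, "arRP", 2565),
    ("PRCD", 5, "arRP", 165),
    ("RD3", 6, "LCA-specific", 588),
    ("RDH12", 6, "LCA-specific", 951),
    ("RGR", 5, "arRP", 876),
    ("RHO", 6, "arRP", 1047),
    ("RLBP1", 6, "arRP", 954),
    ("RP1", 6, "arRP", 6471),
    ("RPE65", 6, "arRP", 1602),
    ("RPGRIP1", 5, "LCA-specific", 3861),
    ("SAG", 6, "arRP", 1218),
    ("TULP1", 6, "arRP", 1626),
    ("USH2A", 6, "arRP", 15606),
]

#: Published rsIDs of the USH2A panel (the one panel named in full); allele
#: pairs are chosen so that the reported shared haplotype CCTGCA is
#: expressible.  All other marker ids and frequencies are synthetic.
_USH2A_MARKERS = [
    ("rs7519402", ("C", "T")),
    ("rs4253963", ("C", "A")),
    ("rs2669053", ("T", "C")),
    ("rs2034960", ("G", "A")),
    ("rs301760", ("C", "G")),
    ("rs1544299", ("A", "G")),
]

_PANEL_SEED = 283615  # fixed: the default panel is a stable package constant


def default_panels() -> list:
    """The 28-gene synthetic default panel.

    Biallelic SNPs with minor-allele frequencies drawn uniform on
    [0.2, 0.5] from a fixed internal seed, so the panel is identical across
    runs and platforms.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    bases = ["A", "C", "G", "T"]
    panels = []
    for gene, n_snps, category, size in _GENE_TABLE:
        markers = []
        for i in range(n_snps):
            if gene == "USH2A":
                marker_id, alleles = _USH2A_MARKERS[i]
            else:
                marker_id = f"{gene}_snp{i + 1}"
                alleles = tuple(rng.choice(bases, size=2, replace=False))
            maf = float(rng.uniform(0.2, 0.5))
            freqs = {alleles[0]: 1.0 - maf, alleles[1]: maf}
            markers.append(
                SnpMarker(marker_id, gene, i, frozenset(alleles), allele_freqs=freqs)
            )
        panels.append(GenePanel(gene, tuple(markers), category=category, transcript_size=size))
    return panels


def informative_panel(gene: str) -> GenePanel:
    """Single-marker panel with four equifrequent alleles.

    When the gene is listed in ``SimulationConfig.informative_genes`` the
    simulator assigns the four alleles to the four founder copies
    deterministically, so founders are always fully informative (father 1/2,
    mother 3/4 after relabeling).
    """
    marker = SnpMarker(
        f"{gene}_m1",
        gene,
        0,
        frozenset({"1", "2", "3", "4"}),
        allele_freqs={a: 0.25 for a in "1234"},
    )
    return GenePanel(gene, (marker,), category="arRP", transcript_size=1000)


@dataclass(frozen=True)
class FamilySpec:
    """Target structure of one simulated family (counts of genotyped sibs)."""

    n_affected: int = 2
    n_unaffected: int = 1
    father_typed: bool = True
    mother_typed: bool = True
    sibship_size: int | None = None  # None -> n_affected + n_unaffected

    def resolved_sibship(self) -> int:
        n = self.n_affected + self.n_unaffected
        return n if self.sibship_size is None else self.sibship_size

    def validate(self) -> None:
        if self.n_affected < 1:
            raise ValueError("family_structure: n_affected must be >= 1")
        if self.n_unaffected < 0:
            raise ValueError("family_structure: n_unaffected must be >= 0")
        if self.resolved_sibship() < self.n_affected + self.n_unaffected:
            raise ValueError(
                "family_structure: sibship_size must be >= n_affected + n_unaffected"
            )


# Marginal structure frequencies of the reference 29-family cohort, used by
# the default per-family structure sampler (affected counts, unaffected
# counts, sibship sizes, parental DNA availability).
_AFFECTED_DIST = {1: 9, 2: 13, 3: 7}
_UNAFFECTED_DIST = {0: 12, 1: 11, 2: 6}
_SIBSHIP_DIST = {2: 4, 3: 12, 4: 8, 5: 5}
_P_MOTHER_TYPED = 24 / 29
_P_FATHER_TYPED = 21 / 29


def default_family_structure(n_families: int, rng: np.random.Generator) -> list:
    """Sample per-family structures from the reference cohort's marginals."""

    def draw(dist):
        keys = list(dist)
        w = np.array([dist[k] for k in keys], dtype=float)
        return keys[rng.choice(len(keys), p=w / w.sum())]

    specs = []
    for _ in range(n_families):
        k = draw(_AFFECTED_DIST)
        u = draw(_UNAFFECTED_DIST)
        sib = max(draw(_SIBSHIP_DIST), k + u)
        specs.append(
            FamilySpec(
                n_affected=k,
                n_unaffected=u,
                father_typed=bool(rng.random() < _P_FATHER_TYPED),
                mother_typed=bool(rng.random() < _P_MOTHER_TYPED),
                sibship_size=sib,
            )
        )
    return specs


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``family_structure`` may be ``None`` (sample each family's structure
    from the reference cohort's marginals), a single :class:`FamilySpec`
    applied to every family, or a sequence of per-family specs.
    """

    n_families: int = 31
    panels: Sequence[GenePanel] = field(default_factory=default_panels)
    causal_gene: str = "USH2A"
    family_structure: object = None
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    false_paternity_families: frozenset = frozenset()
    seed: int = 0
    informative_genes: frozenset = frozenset()
    max_attempts: int = 100_000

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        genes = [p.gene for p in self.panels]
        if len(set(genes)) != len(genes):
            raise ValueError("panels: duplicate gene symbols")
        if self.causal_gene not in genes:
            raise ValueError(f"causal_gene {self.causal_gene!r} not among panels")
        for name in ("penetrance", "phenocopy_rate", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        bad = [i for i in self.false_paternity_families if not 0 <= i < self.n_families]
        if bad:
            raise ValueError(f"false_paternity_families: indices out of range: {bad}")
        for spec in self._specs_or_none() or []:
            spec.validate()
        for g in self.informative_genes:
            panel = next(p for p in self.panels if p.gene == g)
            for m in panel.markers:
                if len(m.alleles) < 4:
                    raise ValueError(
                        f"informative_genes: {g} marker {m.marker_id} needs >=4 alleles"
                    )

    def _specs_or_none(self):
        if self.family_structure is None:
            return None
        if isinstance(self.family_structure, FamilySpec):
            return [self.family_structure] * self.n_families
        specs = list(self.family_structure)
        if len(specs) != self.n_families:
            raise ValueError(
                f"family_structure: {len(specs)} specs for {self.n_families} families"
            )
        return specs


@dataclass
class FamilyTruth:
    """Latent state of one simulated family (pre-error, pre-missingness)."""

    family_id: str
    causal_gene: str
    risk_copies: dict  # {"father": 1|2, "mother": 1|2}
    transmissions: dict  # child_id -> gene -> (maternal copy, paternal copy)
    true_paternity: bool
    founder_haplotypes: dict  # gene -> {"father"/"mother"/("true_father") : [hap1, hap2]}
    latent_affection: dict  # child_id -> true affection before typing selection

    def to_jsonable(self):
        return {
            "family_id": self.family_id,
            "causal_gene": self.causal_gene,
            "risk_copies": self.risk_copies,
            "transmissions": {
                c: {g: list(t) for g, t in genes.items()}
                for c, genes in self.transmissions.items()
            },
            "true_paternity": self.true_paternity,
            "founder_haplotypes": {
                g: {who: [list(h) for h in haps] for who, haps in d.items()}
                for g, d in self.founder_haplotypes.items()
            },
            "latent_affection": self.latent_affection,
        }


@dataclass
class SimulatedCohort:
    families: list
    truth: list  # FamilyTruth per family
    panels: list
    config: SimulationConfig


def sample_founder_haplotype(panel: GenePanel, rng: np.random.Generator) -> tuple:
    """One haplotype drawn marker-by-marker from allele frequencies."""
    hap = []
    for m in panel.markers:
        if m.allele_freqs is None:
            raise ValueError(f"marker {m.marker_id} has no allele frequencies")
        alleles = sorted(m.allele_freqs)
        p = np.array([m.allele_freqs[a] for a in alleles])
        hap.append(alleles[rng.choice(len(alleles), p=p)])
    return tuple(hap)


def _informative_founder_haps(panel: GenePanel):
    """Deterministic fully informative founder copies: father 1/2, mother 3/4."""
    haps = [[], [], [], []]
    for m in panel.markers:
        alleles = sorted(m.alleles)
        for copy in range(4):
            haps[copy].append(alleles[copy])
    haps = [tuple(h) for h in haps]
    return (haps[0], haps[1]), (haps[2], haps[3])


def _apply_noise(genotype: Genotype, marker: SnpMarker, rng, error_rate, missing_rate):
    if genotype.is_missing:
        return genotype
    a, b = genotype.alleles
    if error_rate > 0:
        out = []
        for allele in (a, b):
            if rng.random() < error_rate:
                others = sorted(marker.alleles - {allele})
                allele = others[rng.integers(len(others))]
            out.append(allele)
        a, b = out
    if missing_rate > 0 and rng.random() < missing_rate:
        return Genotype()
    return Genotype(a, b)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort with full truth labels.

    Raises if rejection sampling of any family's affection pattern exceeds
    ``config.max_attempts`` (suggesting the requested structure is too
    improbable under the penetrance/phenocopy settings).
    """
    config.validate()
    specs = config._specs_or_none()
    if specs is None:
        struct_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA]))
        specs = default_family_structure(config.n_families, struct_rng)

    genes = [p.gene for p in config.panels]
    families = []
    truths = []
    for fi in range(config.n_families):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, fi]))
        spec = specs[fi]
        fam_id = f"F{fi + 1:03d}"
        false_pat = fi in config.false_paternity_families

        founder_haps = {}
        for panel in config.panels:
            if panel.gene in config.informative_genes:
                fa, mo = _informative_founder_haps(panel)
            else:
                fa = (sample_founder_haplotype(panel, rng), sample_founder_haplotype(panel, rng))
                mo = (sample_founder_haplotype(panel, rng), sample_founder_haplotype(panel, rng))
            entry = {"father": fa, "mother": mo}
            if false_pat:
                entry["true_father"] = (
                    sample_founder_haplotype(panel, rng),
                    sample_founder_haplotype(panel, rng),
                )
            founder_haps[panel.gene] = entry

        father_risk = int(rng.integers(1, 3))
        mother_risk = int(rng.integers(1, 3))
        sib = spec.resolved_sibship()
        need_pheno = config.penetrance < 1.0 or config.phenocopy_rate > 0.0

        # rejection-sample the causal-gene transmissions / affection pattern
        for attempt in range(config.max_attempts):
            causal_trans = rng.integers(1, 3, size=(sib, 2))  # (maternal, paternal)
            genetic = (causal_trans[:, 0] == mother_risk) & (causal_trans[:, 1] == father_risk)
            if need_pheno:
                u = rng.random(sib)
                affected = np.where(
                    genetic, u < config.penetrance, u < config.phenocopy_rate
                )
            else:
                affected = genetic
            n_aff = int(affected.sum())
            n_unaff = sib - n_aff
            if n_aff >= spec.n_affected and n_unaff >= spec.n_unaffected:
                break
        else:
            raise RuntimeError(
                f"family {fam_id}: affection pattern (>= {spec.n_affected} affected, "
                f">= {spec.n_unaffected} unaffected in sibship of {sib}) not reached in "
                f"{config.max_attempts} attempts; revise penetrance/structure parameters"
            )

        # pick which sibs are genotyped: first n_affected affecteds, first
        # n_unaffected unaffecteds, in sib order
        aff_idx = [i for i in range(sib) if affected[i]][: spec.n_affected]
        unaff_idx = [i for i in range(sib) if not affected[i]][: spec.n_unaffected]
        typed_idx = set(aff_idx) | set(unaff_idx)

        # transmissions at the remaining genes, uniform and independent
        trans_per_child = [
            {config.causal_gene: (int(causal_trans[i, 0]), int(causal_trans[i, 1]))}
            for i in range(sib)
        ]
        for panel in config.panels:
            if panel.gene == config.causal_gene:
                continue
            draws = rng.integers(1, 3, size=(sib, 2))
            for i in range(sib):
                trans_per_child[i][panel.gene] = (int(draws[i, 0]), int(draws[i, 1]))

        father_id, mother_id = "FA", "MO"

        def observed_genotypes(hap_pair_by_gene, rng):
            genos = {}
            for panel in config.panels:
                h1, h2 = hap_pair_by_gene(panel.gene)
                for j, m in enumerate(panel.markers):
                    g = Genotype(h1[j], h2[j])
                    g = _apply_noise(
                        g, m, rng, config.genotype_error_rate, config.missing_rate
                    )
                    if not g.is_missing:
                        genos[m.marker_id] = g
            return genos

        father = Individual(father_id, fam_id, sex="male", affection="unaffected")
        mother = Individual(mother_id, fam_id, sex="female", affection="unaffected")
        if spec.father_typed:
            father.genotypes = observed_genotypes(
                lambda g: founder_haps[g]["father"], rng
            )
        if spec.mother_typed:
            mother.genotypes = observed_genotypes(
                lambda g: founder_haps[g]["mother"], rng
            )

        children = []
        latent_affection = {}
        transmissions = {}
        for i in range(sib):
            cid = f"C{i + 1}"
            latent_affection[cid] = "affected" if affected[i] else "unaffected"
            transmissions[cid] = trans_per_child[i]
            typed = i in typed_idx
            child = Individual(
                cid,
                fam_id,
                father_id=father_id,
                mother_id=mother_id,
                sex="male" if rng.integers(2) else "female",
                affection=latent_affection[cid] if typed else "unknown",
            )
            if typed:
                paternal_key = "true_father" if false_pat else "father"

                def child_haps(gene, i=i, paternal_key=paternal_key):
                    mc, pc = trans_per_child[i][gene]
                    return (
                        founder_haps[gene]["mother"][mc - 1],
                        founder_haps[gene][paternal_key][pc - 1],
                    )

                child.genotypes = observed_genotypes(child_haps, rng)
            children.append(child)

        families.append(NuclearFamily(fam_id, father, mother, children))
        truths.append(
            FamilyTruth(
                family_id=fam_id,
                causal_gene=config.causal_gene,
                risk_copies={"father": father_risk, "mother": mother_risk},
                transmissions=transmissions,
                true_paternity=not false_pat,
                founder_haplotypes=founder_haps,
                latent_affection=latent_affection,
            )
        )
    return SimulatedCohort(families, truths, list(config.panels), config)


def write_fixture(cohort: SimulatedCohort, directory) -> dict:
    """Emit cohort.ped, panel.tsv and truth.json so downstream stages can run
    from disk exactly as users would.  Returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": d / "cohort.ped",
        "panel": d / "panel.tsv",
        "truth": d / "truth.json",
    }
    write_ped(cohort.families, cohort.panels, paths["ped"])
    write_panel(cohort.panels, paths["panel"])
    truth_payload = {
        "causal_gene": cohort.config.causal_gene,
        "seed": cohort.config.seed,
        "false_paternity_families": sorted(
            t.family_id for t in cohort.truth if not t.true_paternity
        ),
        "families": [t.to_jsonable() for t in cohort.truth],
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2))
    return paths


# ---------------------------------------------------------------------------
# YAML config loading (CLI surface)

_CONFIG_FIELDS = {
    "n_families",
    "panels",
    "causal_gene",
    "family_structure",
    "penetrance",
    "phenocopy_rate",
    "genotype_error_rate",
    "missing_rate",
    "false_paternity_families",
    "seed",
    "informative_genes",
    "max_attempts",
}


def config_from_mapping(data: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML/JSON mapping.

    Raises ``ValueError`` naming the offending field on schema problems.
    ``panels`` may be ``"default"`` or a panel TSV path; ``family_structure``
    may be ``"default"``, one mapping, or a list of mappings with
    :class:`FamilySpec` field names.
    """
    from .pedigree import read_panel

    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    kwargs = dict(data)
    panels = kwargs.pop("panels", "default")
    kwargs["panels"] = default_panels() if panels in (None, "default") else read_panel(panels)
    structure = kwargs.pop("family_structure", None)
    if structure in (None, "default"):
        kwargs["family_structure"] = None
    elif isinstance(structure, Mapping):
        kwargs["family_structure"] = FamilySpec(**structure)
    else:
        try:
            kwargs["family_structure"] = [FamilySpec(**s) for s in structure]
        except TypeError as exc:
            raise ValueError(f"family_structure: {exc}") from exc
    for name in ("false_paternity_families", "informative_genes"):
        if name in kwargs:
            kwargs[name] = frozenset(kwargs[name])
    try:
        config = SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"config: {exc}") from exc
    config.validate()
    return config


def load_config(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_mapping(data)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
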