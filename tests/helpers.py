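"""Shared test builders and the naive phase-enumeration oracle.

The oracle loops over *every* pair of parental haplotype vectors (over the
full alphabet including the missing wildcard) and every transmission
vector, sharing no code with the package's enumeration, so the two can be
compared on randomized instances.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from snpcoseg.pedigree import (
    MISSING,
    GenePanel,
    Genotype,
    Individual,
    NuclearFamily,
    SnpMarker,
)

_PAIRS = ((1, 1), (1, 2), (2, 1), (2, 2))


def make_panel(gene="G1", marker_alleles=("AG",), freqs=None, **kw):
    """Panel from compact allele strings, e.g. ("AG", "CT")."""
    markers = []
    for i, alleles in enumerate(marker_alleles):
        f = None
        if freqs is not None:
            f = dict(zip(alleles, freqs[i]))
        markers.append(
            SnpMarker(f"{gene}_m{i}", gene, i, frozenset(alleles), allele_freqs=f)
        )
    return GenePanel(gene, tuple(markers), **kw)


def _genos(panel, spec):
    """Genotype map from strings like 'A/G C/T' ('0/0' = missing)."""
    out = {}
    if spec is None:
        return out
    for m, g in zip(panel.markers, spec.split()):
        a, b = g.split("/")
        a = MISSING if a == "0" else a
        b = MISSING if b == "0" else b
        geno = Genotype(a, b)
        if not geno.is_missing:
            out[m.marker_id] = geno
    return out


def make_family(panel, father=None, mother=None, children=(), family_id="FAM1"):
    """Family from compact genotype strings.

    *children* is a sequence of (genotype string or None, affection).
    ``father``/``mother`` may be None for an absent parent.
    """
    fa = mo = None
    if father is not None:
        fa = Individual("FA", family_id, sex="male", affection="unaffected",
                        genotypes=_genos(panel, father))
    if mother is not None:
        mo = Individual("MO", family_id, sex="female", affection="unaffected",
                        genotypes=_genos(panel, mother))
    kids = []
    for i, (g, aff) in enumerate(children):
        kids.append(
            Individual(
                f"C{i + 1}",
                family_id,
                father_id="FA" if fa is not None else "FA0",
                mother_id="MO" if mo is not None else "MO0",
                affection=aff,
                genotypes=_genos(panel, g),
            )
        )
    return NuclearFamily(family_id, fa, mo, kids)


# ---------------------------------------------------------------------------
# naive oracle


def canon_tuple(f1, f2, m1, m2, trans):
    """Canonical plain-tuple form under independent parent label swaps."""
    best = None
    for sf, sm in product((False, True), repeat=2):
        fa = (f2, f1) if sf else (f1, f2)
        mo = (m2, m1) if sm else (m1, m2)
        t = tuple(
            (3 - mc if sm else mc, 3 - pc if sf else pc) for mc, pc in trans
        )
        cand = (fa, mo, t)
        if best is None or cand < best:
            best = cand
    return best


def assignment_to_tuple(a):
    return canon_tuple(
        a.father.hap1, a.father.hap2, a.mother.hap1, a.mother.hap2, a.transmissions
    )


def oracle_assignments(family, panel, canonical=True):
    """All consistent assignments by brute force over full haplotype space."""
    alphabet = [sorted(m.alleles) + [MISSING] for m in panel.markers]
    all_haps = list(product(*alphabet))

    def parent_pairs(parent):
        pairs = []
        for h1 in all_haps:
            for h2 in all_haps:
                ok = True
                for i, m in enumerate(panel.markers):
                    g = parent.genotype(m.marker_id) if parent is not None else Genotype()
                    if g.is_missing:
                        if h1[i] != MISSING or h2[i] != MISSING:
                            ok = False
                            break
                    elif tuple(sorted((h1[i], h2[i]))) != g.alleles:
                        ok = False
                        break
                if ok:
                    pairs.append((h1, h2))
        return pairs

    def match(h, x):
        return h == MISSING or h == x

    results = set()
    for f1, f2 in parent_pairs(family.father):
        for m1, m2 in parent_pairs(family.mother):
            for trans in product(_PAIRS, repeat=len(family.children)):
                ok = True
                for child, (mc, pc) in zip(family.children, trans):
                    mh = (m1, m2)[mc - 1]
                    ph = (f1, f2)[pc - 1]
                    for i, m in enumerate(panel.markers):
                        g = child.genotype(m.marker_id)
                        if g.is_missing:
                            continue
                        a, b = g.alleles
                        if not (
                            (match(mh[i], a) and match(ph[i], b))
                            or (match(mh[i], b) and match(ph[i], a))
                        ):
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    if canonical:
                        results.add(canon_tuple(f1, f2, m1, m2, trans))
                    else:
                        results.add(((f1, f2), (m1, m2), trans))
    return results


def random_instance(rng: np.random.Generator):
    """A random (family, panel): <=3 markers, <=4 children, arbitrary calls."""
    n_markers = int(rng.integers(1, 4))
    marker_alleles = []
    for _ in range(n_markers):
        k = int(rng.integers(2, 4))
        marker_alleles.append("".join(rng.choice(list("ACGT"), size=k, replace=False)))
    panel = make_panel("G1", tuple(marker_alleles))

    def geno_string(present_p=0.85):
        parts = []
        for alleles in marker_alleles:
            if rng.random() > present_p:
                parts.append("0/0")
            else:
                a = alleles[rng.integers(len(alleles))]
                b = alleles[rng.integers(len(alleles))]
                parts.append(f"{a}/{b}")
        return " ".join(parts)

    father = geno_string() if rng.random() < 0.85 else None
    mother = geno_string() if rng.random() < 0.85 else None
    n_children = int(rng.integers(1, 5))
    affs = ["affected", "unaffected", "unknown"]
    children = [
        (geno_string(), affs[rng.integers(3)]) for _ in range(n_children)
    ]
    # ascertainment: make the first child affected
    children[0] = (children[0][0], "affected")
    return make_family(panel, father, mother, children), panel
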