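"""Gene-family refinement and cross-taxon sharing summaries.

Family membership normally comes from an external orthology run supplied
as a membership map; a simple single-linkage protein clustering is provided
so synthetic runs are end-to-end.  Refinement applies, in order: a
length band of 50–150% of the family's mean protein length, then a ciliate
proportion >= 95%, >= 5 members, and >= 2 ciliate genera.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TaxonProfile:
    taxon_id: str
    genus: str
    taxon_class: str
    category: str  # EF | NEF | HE | KA
    data_type: str = "transcriptome"  # transcriptome | genome
    ciliate: bool = True


@dataclass(frozen=True)
class FamilyMember:
    record_id: str
    taxon: str
    length: int  # protein length, aa
    ciliate: bool = True


@dataclass
class GeneFamily:
    family_id: str
    members: list
    provenance: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("gene family must be nonempty")


@dataclass
class RefinementResult:
    kept: bool
    family: GeneFamily
    reason: str | None  # None when kept
    dropped_members: list = field(default_factory=list)


# ---------------------------------------------------------------------- #


def protein_identity(a: str, b: str) -> float:
    """Global alignment identity over the longer sequence; gaps mismatch."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / max(len(a), len(b)))


def cluster_orfs(orfs, threshold: float) -> dict:
    """Single-linkage components over protein identity >= threshold.

    Stand-in for an external orthology pipeline; returns
    {family_id: [record ids]} with deterministic ids and ordering.
    """
    if not orfs:
        raise ValueError("need at least one ORF to cluster")
    orfs = sorted(orfs, key=lambda o: o.record_id)
    parent = list(range(len(orfs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            if protein_identity(orfs[i].protein, orfs[j].protein) >= threshold:
                parent[find(i)] = find(j)

    comps: dict[int, list] = {}
    for i, orf in enumerate(orfs):
        comps.setdefault(find(i), []).append(orf.record_id)
    families = sorted((sorted(m) for m in comps.values()), key=lambda m: m[0])
    return {f"F{k:05d}": members for k, members in enumerate(families, 1)}


# ---------------------------------------------------------------------- #


def refine_family(
    family: GeneFamily,
    size_band: tuple = (0.5, 1.5),
    min_ciliate_prop: float = 0.95,
    min_members: int = 5,
    min_genera: int = 2,
    taxa: dict | None = None,
    proportion_before_band: bool = False,
) -> RefinementResult:
    """Apply the two-step refinement rule.

    Step 1 drops members outside [lo*mean, hi*mean] of the mean protein
    length computed once over the initial membership.  Step 2 requires, on
    the survivors, ciliate proportion, member count and distinct ciliate
    genus count.  ``taxa`` maps taxon id -> TaxonProfile; without it the
    member's own ciliate flag is used and genus falls back to the taxon id.
    """
    members = list(family.members)
    if any(m.length <= 0 for m in members):
        raise ValueError("member protein lengths must be positive")
    mean_len = float(np.mean([m.length for m in members]))
    lo, hi = size_band[0] * mean_len, size_band[1] * mean_len
    surviving = [m for m in members if lo <= m.length <= hi]
    dropped = [m for m in members if not (lo <= m.length <= hi)]

    def _is_ciliate(m):
        if taxa is not None and m.taxon in taxa:
            return taxa[m.taxon].ciliate
        return m.ciliate

    def _genus(m):
        if taxa is not None and m.taxon in taxa:
            return taxa[m.taxon].genus
        return m.taxon

    pool = members if proportion_before_band else surviving
    prop = (sum(_is_ciliate(m) for m in pool) / len(pool)) if pool else 0.0

    if not surviving:
        return RefinementResult(False, family, "min_members", dropped)
    refined = GeneFamily(family.family_id, surviving, provenance=family.provenance)

    if prop < min_ciliate_prop:
        return RefinementResult(False, refined, "ciliate_proportion", dropped)
    if len(surviving) < min_members:
        return RefinementResult(False, refined, "min_members", dropped)
    genera = {_genus(m) for m in surviving if _is_ciliate(m)}
    if len(genera) < min_genera:
        return RefinementResult(False, refined, "min_genera", dropped)
    return RefinementResult(True, refined, None, dropped)


# ---------------------------------------------------------------------- #


def presence_matrix(families: list, taxa: list) -> pd.DataFrame:
    """Families x taxa member-count matrix (binarise with ``> 0``).

    ``taxa`` fixes the column order; families are rows in id order.
    """
    taxon_ids = [t.taxon_id if isinstance(t, TaxonProfile) else t for t in taxa]
    data = {}
    for fam in sorted(families, key=lambda f: f.family_id):
        row = dict.fromkeys(taxon_ids, 0)
        for m in fam.members:
            if m.taxon in row:
                row[m.taxon] += 1
        data[fam.family_id] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=taxon_ids).fillna(0).astype(int)


def sharing_summary(matrix: pd.DataFrame, taxa: list) -> dict:
    """Upset-style sharing counts and size summaries per category and taxon.

    ``matrix`` may be binary presence or member counts (presence is
    ``> 0``; size statistics use the counts as given).
    """
    if matrix.empty:
        raise ValueError("presence matrix is nonempty by contract")
    profiles = {t.taxon_id: t for t in taxa}
    cat_of = {tid: profiles[tid].category for tid in matrix.columns if tid in profiles}
    cls_of = {tid: profiles[tid].taxon_class for tid in matrix.columns if tid in profiles}

    upset: dict[str, int] = {}
    per_family_cats = {}
    per_family_classes = {}
    for fam, row in matrix.iterrows():
        present = [t for t in matrix.columns if row[t] > 0]
        cats = sorted({cat_of[t] for t in present if t in cat_of})
        per_family_cats[fam] = cats
        per_family_classes[fam] = sorted({cls_of[t] for t in present if t in cls_of})
        key = "&".join(cats) if cats else "(none)"
        upset[key] = upset.get(key, 0) + 1

    per_category = {}
    categories = sorted({c for cats in per_family_cats.values() for c in cats})
    for cat in categories:
        cat_taxa = [t for t in matrix.columns if cat_of.get(t) == cat]
        fams = [f for f, cats in per_family_cats.items() if cat in cats]
        sizes = [int(matrix.loc[f, cat_taxa].sum()) for f in fams]
        per_category[cat] = {
            "n_families": len(fams),
            "mean_size": float(np.mean(sizes)) if sizes else 0.0,
            "median_size": float(np.median(sizes)) if sizes else 0.0,
        }

    per_taxon = {}
    for t in matrix.columns:
        present = matrix[t] > 0
        sizes = matrix.loc[present, t]
        per_taxon[t] = {
            "n_families": int(present.sum()),
            "mean_size": float(sizes.mean()) if present.any() else 0.0,
        }

    return {
        "upset": upset,
        "per_category": per_category,
        "per_taxon": per_taxon,
        "categories_per_family": per_family_cats,
        "classes_per_family": per_family_classes,
        "n_families": int(matrix.shape[0]),
    }
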