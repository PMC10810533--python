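"""End-to-end pipeline orchestration.

Stage order follows the analysis narrative: curate -> compose -> families
-> history -> selection -> report (preceded by simulate when running on
synthetic inputs).  Every stage reads its inputs from the run directory
and writes fixed-name outputs there, so a run is resumable from any
intermediate; ``manifest.json`` records the configuration, seeds and
per-stage record counts and fully determines the run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .codes import get_code
from .composition import PercentileBand, composition_band_filter, composition_stats
from .families import FamilyMember, GeneFamily, TaxonProfile, cluster_orfs, presence_matrix, refine_family, sharing_summary
from .history import branch_event_table, dollo_gain_map, reconcile_gene_tree
from .orf import call_orfs, dedupe_allelic_variants
from .selection import adjust_fdr, choose_reference_group, fit_busted_s, fit_relax_groups, group_branch_counts, label_branches
from .simulate import (
    SimulationConfig,
    emit_transcriptomes,
    simulate_codon_alignments,
    simulate_family_histories,
    simulate_reference_gc3s,
    simulate_species_tree,
    taxon_profiles,
)
from .trees import newick_string, read_tree

STAGES = ("simulate", "curate", "compose", "families", "history", "selection", "report")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """One run = one config; exactly one of ``simulate``/``inputs`` active."""

    outdir: str
    seed: int = 1
    simulate: SimulationConfig | None = None
    inputs: dict | None = None  # fasta_dir, taxon_table, species_tree, reference_gc3s, [gene_tree_dir, alignment_dir]
    genetic_code: int = 6
    min_aa: int = 200
    complete_only: bool = True
    allele_identity: float = 0.97
    band_lower: float = 10.0
    band_upper: float = 90.0
    cluster_threshold: float = 0.5
    size_band: tuple = (0.5, 1.5)
    min_ciliate_prop: float = 0.95
    min_members: int = 5
    min_genera: int = 2
    q_threshold: float = 0.1
    bin_increment: int = 5
    n_starts: int = 2
    selection_max_families: int | None = None

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' and 'inputs' must be set")
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        if not 0 <= self.band_lower <= self.band_upper <= 100:
            raise ValueError("band percentiles must satisfy 0 <= lower <= upper <= 100")

    @classmethod
    def tiny_synthetic(cls, outdir, seed: int = 1) -> "RunConfig":
        """Desk-scale synthetic run: 8 taxa, 30 families, 100 codons."""
        return cls(
            outdir=str(outdir),
            seed=seed,
            simulate=SimulationConfig(
                n_taxa=8,
                category_scheme={"EF": 0.375, "NEF": 0.25, "HE": 0.25, "KA": 0.125},
                n_families=30,
                n_codons=100,
                seed=seed,
            ),
            min_aa=60,
            min_members=3,
            selection_max_families=2,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "size_band" in data:
            data["size_band"] = tuple(data["size_band"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            if sim.get("codon_frequencies") is not None:
                sim["codon_frequencies"] = [float(x) for x in sim["codon_frequencies"]]
            d["simulate"] = sim
        return d


def _outdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _update_manifest(config: RunConfig, stage: str, info: dict) -> None:
    path = _outdir(config) / "manifest.json"
    echo = config.to_dict()
    echo["outdir"] = "."  # keep the manifest portable across run directories
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__,
        "config": echo,
        "stages": {},
    }
    manifest["stages"][stage] = info
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------- #
# Stages
# ---------------------------------------------------------------------- #


def stage_simulate(config: RunConfig) -> dict:
    cfg = config.simulate
    out = _outdir(config) / "simulate"
    out.mkdir(exist_ok=True)
    (out / "families_true").mkdir(exist_ok=True)

    sim = simulate_species_tree(cfg.n_taxa, cfg.category_scheme, seed=cfg.seed, mean_branch_length=cfg.mean_branch_length)
    (out / "species_tree.nwk").write_text(newick_string(sim.tree) + "\n")
    profiles = taxon_profiles(sim)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "taxon": p.taxon_id,
                    "genus": p.genus,
                    "class": p.taxon_class,
                    "category": p.category,
                    "data_type": p.data_type,
                    "ciliate": int(p.ciliate),
                }
                for p in profiles
            ]
        ),
        out / "taxa.tsv",
    )

    hists = simulate_family_histories(sim, cfg, cfg.n_families)
    seeds = np.random.default_rng(cfg.seed + 17).integers(0, 2**31 - 1, size=len(hists))
    records: dict = {t: [] for t in sim.leaf_categories}
    n_extinct = 0
    hist_rows = []
    for h, s in zip(hists, seeds):
        hist_rows.append(
            {
                "family_id": h.family_id,
                "birth_node": h.birth_node,
                "n_losses": len(h.loss_branches),
                "n_duplication_events": sum(c for _, c in h.duplication_events),
                "n_surviving_leaves": len(h.surviving_leaves),
                "extinct": int(h.extinct),
            }
        )
        if h.extinct:
            n_extinct += 1
            continue
        aln, gene_tree = simulate_codon_alignments(h, cfg, seed=int(s), sim=sim)
        with open(out / "families_true" / f"{h.family_id}.fasta", "w") as fh:
            for name in sorted(aln):
                fh.write(f">{name}\n{aln[name]}\n")
        if len(aln) >= 2:
            (out / "families_true" / f"{h.family_id}.nwk").write_text(newick_string(gene_tree) + "\n")
        for name, cds in aln.items():
            records[name.split(".")[0]].append((h.family_id, name, cds))
    _write_tsv(pd.DataFrame(hist_rows), out / "histories.tsv")

    truth = emit_transcriptomes(records, cfg, out, birth_nodes={h.family_id: h.birth_node for h in hists}, seed=cfg.seed + 29)
    reference = simulate_reference_gc3s(cfg, seed=cfg.seed + 31)
    (out / "reference_gc3s.txt").write_text("".join(f"{v:.6f}\n" for v in reference))
    return {
        "n_taxa": cfg.n_taxa,
        "n_families": cfg.n_families,
        "n_extinct": n_extinct,
        "n_transcripts": int(len(truth)),
        "seed": cfg.seed,
    }


def _input_paths(config: RunConfig) -> dict:
    if config.simulate is not None:
        out = _outdir(config) / "simulate"
        return {
            "fasta_dir": out,
            "taxon_table": out / "taxa.tsv",
            "species_tree": out / "species_tree.nwk",
            "reference_gc3s": out / "reference_gc3s.txt",
            "alignment_dir": out / "families_true",
            "gene_tree_dir": out / "families_true",
        }
    return {k: Path(v) for k, v in config.inputs.items()}


def load_taxa(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        row.taxon: TaxonProfile(
            taxon_id=row.taxon,
            genus=row.genus,
            taxon_class=row["class"],
            category=row.category,
            data_type=row.data_type,
            ciliate=bool(row.ciliate),
        )
        for _, row in df.iterrows()
    }


def stage_curate(config: RunConfig) -> dict:
    paths = _input_paths(config)
    out = _outdir(config) / "curate"
    out.mkdir(exist_ok=True)
    code = get_code(config.simulate.genetic_code if config.simulate else config.genetic_code)
    taxa = load_taxa(paths["taxon_table"])

    rows = []
    n_transcripts = 0
    with open(out / "curated.fasta", "w") as fasta_out:
        for taxon in sorted(taxa):
            fasta = Path(paths["fasta_dir"]) / f"{taxon}.fasta"
            if not fasta.exists():
                continue
            orfs = []
            for rec in SeqIO.parse(str(fasta), "fasta"):
                n_transcripts += 1
                called = call_orfs(
                    str(rec.seq), code, min_aa=config.min_aa, complete_only=config.complete_only,
                    record_id=rec.id, taxon=taxon, source_id=rec.id,
                )
                orfs.extend(called)
            reps, clusters = dedupe_allelic_variants(orfs, identity=config.allele_identity)
            rep_ids = {r.record_id for r in reps}
            for orf in orfs:
                rows.append(
                    {
                        "record_id": orf.record_id,
                        "taxon": taxon,
                        "frame": orf.frame,
                        "start": orf.start,
                        "end": orf.end,
                        "aa_len": len(orf.protein),
                        "representative": int(orf.record_id in rep_ids),
                    }
                )
            for rep in sorted(reps, key=lambda r: r.record_id):
                fasta_out.write(f">{rep.record_id} taxon={taxon}\n{rep.nucleotide}\n")
    df = pd.DataFrame(rows, columns=["record_id", "taxon", "frame", "start", "end", "aa_len", "representative"])
    _write_tsv(df, out / "orfs.tsv")
    return {
        "n_transcripts": n_transcripts,
        "n_orfs": int(len(df)),
        "n_representatives": int(df["representative"].sum()) if len(df) else 0,
    }


def _read_curated(config: RunConfig):
    out = _outdir(config) / "curate"
    code = get_code(config.simulate.genetic_code if config.simulate else config.genetic_code)
    orfs = []
    for rec in SeqIO.parse(str(out / "curated.fasta"), "fasta"):
        taxon = rec.description.split("taxon=")[1].split()[0]
        from .orf import OrfRecord

        cds = str(rec.seq)
        orfs.append(
            OrfRecord(
                record_id=rec.id,
                taxon=taxon,
                nucleotide=cds,
                protein=code.translate(cds),
                frame=1,
                source_id=rec.id,
                start=0,
                end=len(cds),
            )
        )
    return orfs, code


def stage_compose(config: RunConfig) -> dict:
    paths = _input_paths(config)
    out = _outdir(config) / "compose"
    out.mkdir(exist_ok=True)
    orfs, code = _read_curated(config)
    reference = [float(x) for x in Path(paths["reference_gc3s"]).read_text().split()]
    band = PercentileBand.from_reference(reference, config.band_lower, config.band_upper)
    stats = [composition_stats(o, code) for o in orfs]
    kept, discarded = composition_band_filter(stats, reference, band=band)
    reason = {s.record_id: r for s, r in discarded}
    taxon_of = {o.record_id: o.taxon for o in orfs}
    df = pd.DataFrame(
        [
            {
                "record_id": s.record_id,
                "taxon": taxon_of[s.record_id],
                "n_codons": s.n_codons,
                "gc3s": s.gc3s,
                "enc": s.enc,
                "kept": int(s.record_id not in reason),
                "reason": reason.get(s.record_id, ""),
            }
            for s in stats
        ],
        columns=["record_id", "taxon", "n_codons", "gc3s", "enc", "kept", "reason"],
    )
    _write_tsv(df, out / "composition.tsv")
    return {
        "band_lower_gc3s": band.lower,
        "band_upper_gc3s": band.upper,
        "n_candidates": len(stats),
        "n_kept": len(kept),
        "n_discarded": len(discarded),
    }


def stage_families(config: RunConfig) -> dict:
    paths = _input_paths(config)
    out = _outdir(config) / "families"
    out.mkdir(exist_ok=True)
    orfs, code = _read_curated(config)
    comp = pd.read_csv(_outdir(config) / "compose" / "composition.tsv", sep="\t")
    kept_ids = set(comp.loc[comp.kept == 1, "record_id"])
    orfs = [o for o in orfs if o.record_id in kept_ids]
    taxa = load_taxa(paths["taxon_table"])

    membership = cluster_orfs(orfs, config.cluster_threshold) if orfs else {}
    by_id = {o.record_id: o for o in orfs}
    fam_rows = []
    refined = []
    refine_rows = []
    for fid, members in membership.items():
        family = GeneFamily(
            fid,
            [FamilyMember(r, by_id[r].taxon, len(by_id[r].protein), ciliate=taxa[by_id[r].taxon].ciliate) for r in members],
        )
        res = refine_family(
            family,
            size_band=config.size_band,
            min_ciliate_prop=config.min_ciliate_prop,
            min_members=config.min_members,
            min_genera=config.min_genera,
            taxa=taxa,
        )
        refine_rows.append(
            {
                "family_id": fid,
                "n_initial": len(members),
                "n_refined": len(res.family.members),
                "kept": int(res.kept),
                "reason": res.reason or "",
            }
        )
        for r in members:
            fam_rows.append({"family_id": fid, "record_id": r})
        if res.kept:
            refined.append(res.family)
    _write_tsv(pd.DataFrame(fam_rows, columns=["family_id", "record_id"]), out / "families.tsv")
    _write_tsv(pd.DataFrame(refine_rows), out / "refined.tsv")

    profiles = sorted(taxa.values(), key=lambda p: p.taxon_id)
    if refined:
        matrix = presence_matrix(refined, profiles)
        matrix.index.name = "family_id"
        _write_tsv(matrix, out / "presence.tsv", index=True)
        summary = sharing_summary(matrix, profiles)
    else:
        matrix = pd.DataFrame(columns=[p.taxon_id for p in profiles])
        matrix.index.name = "family_id"
        _write_tsv(matrix, out / "presence.tsv", index=True)
        summary = {"upset": {}, "per_category": {}, "per_taxon": {}, "n_families": 0}
    (out / "sharing.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    # map refined families back to dominant true simulated family (synthetic runs)
    mapping_rows = []
    for fam in refined:
        parts = [m.record_id.split(".") for m in fam.members]
        true_ids = [p[1] for p in parts if len(p) >= 3 and p[1].startswith("fam")]
        dominant = max(set(true_ids), key=true_ids.count) if true_ids else ""
        mapping_rows.append({"family_id": fam.family_id, "true_family": dominant})
    _write_tsv(pd.DataFrame(mapping_rows, columns=["family_id", "true_family"]), out / "family_map.tsv")
    return {"n_clusters": len(membership), "n_refined": len(refined)}


def stage_history(config: RunConfig) -> dict:
    paths = _input_paths(config)
    out = _outdir(config) / "history"
    out.mkdir(exist_ok=True)
    species = read_tree(paths["species_tree"])
    presence = pd.read_csv(_outdir(config) / "families" / "presence.tsv", sep="\t", index_col=0)

    if len(presence):
        gains, births = dollo_gain_map(presence, species)
    else:
        gains, births = {}, {}
    _write_tsv(
        pd.DataFrame([{"family_id": f, "birth_node": b} for f, b in sorted(births.items())],
                     columns=["family_id", "birth_node"]),
        out / "births.tsv",
    )

    recs = []
    fam_map = pd.read_csv(_outdir(config) / "families" / "family_map.tsv", sep="\t").fillna("")
    gene_tree_dir = Path(paths.get("gene_tree_dir", ""))
    n_reconciled = 0
    for _, row in fam_map.iterrows():
        true_fam = row.true_family
        if not true_fam:
            continue
        nwk = gene_tree_dir / f"{true_fam}.nwk"
        if not nwk.exists():
            continue
        rm = reconcile_gene_tree(read_tree(nwk), species)
        recs.append(rm)
        n_reconciled += 1
    events = branch_event_table(gains, recs)
    _write_tsv(events.reset_index(), out / "branch_events.tsv")
    return {
        "n_families_dated": len(births),
        "n_reconciled": n_reconciled,
        "total_gains": int(sum(gains.values())) if gains else 0,
        "total_duplications": int(events["duplications"].sum()) if len(events) else 0,
    }


def stage_selection(config: RunConfig) -> dict:
    paths = _input_paths(config)
    out = _outdir(config) / "selection"
    out.mkdir(exist_ok=True)
    taxa = load_taxa(paths["taxon_table"])
    categories = {t: p.category for t, p in taxa.items()}
    code = config.simulate.genetic_code if config.simulate else config.genetic_code

    fam_map = pd.read_csv(_outdir(config) / "families" / "family_map.tsv", sep="\t").fillna("")
    aln_dir = Path(paths["alignment_dir"])
    tree_dir = Path(paths["gene_tree_dir"])
    targets = []
    for _, row in fam_map.iterrows():
        if not row.true_family:
            continue
        fa = aln_dir / f"{row.true_family}.fasta"
        nwk = tree_dir / f"{row.true_family}.nwk"
        if fa.exists() and nwk.exists():
            targets.append((row.family_id, row.true_family, fa, nwk))
    if config.selection_max_families:
        targets = targets[: config.selection_max_families]

    relax_rows = []
    busted_rows = []
    rng = np.random.default_rng(config.seed + 41)
    for family_id, true_fam, fa, nwk in targets:
        aln = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fa), "fasta")}
        gene_tree = read_tree(nwk)
        try:
            partition = label_branches(gene_tree, categories)
        except KeyError:
            continue
        reference, testable = choose_reference_group(partition)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        if testable:
            res = fit_relax_groups(aln, gene_tree, partition, code=code, n_starts=config.n_starts, seed=fit_seed)
            for g in res.groups:
                if g == res.reference:
                    continue
                relax_rows.append(
                    {
                        "family_id": family_id,
                        "reference": res.reference,
                        "group": g,
                        "k": res.k.get(g, math.nan),
                        "lnl_null": res.lnl_null,
                        "lnl_alt": res.lnl_alt,
                        "lrt": res.lrt,
                        "df": res.df,
                        "p": res.p,
                        "fit_check": int(bool(res.fit_check)),
                    }
                )
        counts = group_branch_counts(partition)
        for g in sorted(counts):
            if counts[g] < 2:
                continue
            bres = fit_busted_s(aln, gene_tree, partition, g, code=code, n_starts=1, seed=fit_seed + 1)
            busted_rows.append(
                {
                    "family_id": family_id,
                    "group": g,
                    "n_branches": bres.n_branches,
                    "lnl_unconstrained": bres.lnl_unconstrained,
                    "lnl_constrained": bres.lnl_constrained,
                    "lrt": bres.lrt,
                    "p": bres.p,
                    "omega3": bres.omega3,
                    "weight3": bres.weight3,
                }
            )

    relax = pd.DataFrame(relax_rows, columns=["family_id", "reference", "group", "k", "lnl_null", "lnl_alt", "lrt", "df", "p", "fit_check"])
    if len(relax):
        per_family = relax.drop_duplicates("family_id")[["family_id", "p"]]
        qmap = dict(zip(per_family.family_id, adjust_fdr(per_family.p)))
        relax["q"] = relax.family_id.map(qmap)
    else:
        relax["q"] = []
    _write_tsv(relax, out / "relax.tsv")

    busted = pd.DataFrame(busted_rows, columns=["family_id", "group", "n_branches", "lnl_unconstrained", "lnl_constrained", "lrt", "p", "omega3", "weight3"])
    busted["q"] = adjust_fdr(busted.p) if len(busted) else []
    _write_tsv(busted, out / "busted.tsv")
    return {
        "n_families_fit": len(targets),
        "n_relax_tests": int(relax.family_id.nunique()) if len(relax) else 0,
        "n_relax_significant": int((relax.drop_duplicates("family_id").q <= config.q_threshold).sum()) if len(relax) else 0,
        "n_busted_tests": len(busted),
    }


def stage_report(config: RunConfig) -> dict:
    out = _outdir(config) / "report"
    out.mkdir(exist_ok=True)
    base = _outdir(config)
    sharing = json.loads((base / "families" / "sharing.json").read_text())

    # (a) per-category family counts and sizes
    cat_rows = [
        {"category": c, **vals} for c, vals in sorted(sharing.get("per_category", {}).items())
    ]
    _write_tsv(pd.DataFrame(cat_rows, columns=["category", "n_families", "mean_size", "median_size"]), out / "category_sizes.tsv")

    # (b) sharing/upset table
    upset_rows = [{"categories": k, "n_families": v} for k, v in sorted(sharing.get("upset", {}).items())]
    _write_tsv(pd.DataFrame(upset_rows, columns=["categories", "n_families"]), out / "sharing.tsv")

    # (c) per-branch gains/duplications
    events = pd.read_csv(base / "history" / "branch_events.tsv", sep="\t")
    _write_tsv(events, out / "branch_events.tsv")

    # (d) Table-1-shaped selection summary
    busted = pd.read_csv(base / "selection" / "busted.tsv", sep="\t")
    sel_rows = []
    for group, sub in busted.groupby("group"):
        n_sel = int((sub.q <= config.q_threshold).sum())
        sel_rows.append(
            {
                "group": group,
                "genes": len(sub),
                "mean_branches": float(sub.n_branches.mean()),
                "positively_selected": n_sel,
                "proportion": round(n_sel / len(sub), 3),
            }
        )
    _write_tsv(pd.DataFrame(sel_rows, columns=["group", "genes", "mean_branches", "positively_selected", "proportion"]), out / "selection_summary.tsv")

    # per-bin EDS detection rates (bins of labeled-branch counts)
    if len(busted):
        from .selection import BustedResult, bin_eds_rates

        results = [
            BustedResult(r.group, int(r.n_branches), r.lnl_unconstrained, r.lnl_constrained, r.lrt, r.p, q=r.q)
            for r in busted.itertuples()
        ]
        bins = bin_eds_rates(results, increment=config.bin_increment, q_threshold=config.q_threshold)
    else:
        bins = pd.DataFrame(columns=["group", "bin", "n", "rate"])
    _write_tsv(bins, out / "eds_bins.tsv")

    # descriptive group-size comparisons (routine statistics)
    stats_block = {}
    presence = pd.read_csv(base / "families" / "presence.tsv", sep="\t", index_col=0)
    if len(presence) and sharing.get("per_category"):
        from scipy import stats as sps

        taxa = load_taxa(_input_paths(config)["taxon_table"])
        groups_sizes = {}
        for cat in sorted({p.category for p in taxa.values()}):
            cols = [t for t in presence.columns if taxa[t].category == cat]
            if not cols:
                continue
            sub = presence[cols].to_numpy()
            sizes = sub.sum(axis=1)[sub.sum(axis=1) > 0]
            if len(sizes):
                groups_sizes[cat] = sizes
        if len(groups_sizes) >= 2:
            arrays = list(groups_sizes.values())
            try:
                stats_block["anova_p"] = float(sps.f_oneway(*arrays).pvalue)
                stats_block["kruskal_p"] = float(sps.kruskal(*arrays).pvalue)
            except ValueError:
                pass

    report = {
        "n_families": sharing.get("n_families", 0),
        "per_category": sharing.get("per_category", {}),
        "selection_summary": sel_rows,
        "group_size_tests": stats_block,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {"n_families": sharing.get("n_families", 0), "n_selection_groups": len(sel_rows)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "compose": stage_compose,
    "families": stage_families,
    "history": stage_history,
    "selection": stage_selection,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, from_stage: str | None = None) -> dict:
    """Run all stages in order (optionally resuming at ``from_stage``);
    returns the manifest."""
    stages = [s for s in STAGES if config.simulate is not None or s != "simulate"]
    if from_stage is not None:
        if from_stage not in stages:
            raise ValueError(f"unknown stage {from_stage!r}")
        stages = stages[stages.index(from_stage):]
    for stage in stages:
        try:
            info = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _update_manifest(config, stage, info)
    return json.loads((_outdir(config) / "manifest.json").read_text())


def write_report(config: RunConfig) -> dict:
    """Regenerate the report tables from existing stage outputs."""
    return stage_report(config)
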