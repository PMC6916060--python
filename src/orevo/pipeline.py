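"""End-to-end orchestration: simulate -> mine -> classify -> gainloss -> stats.

One run directory with a subfolder per stage, TSV/FASTA at the stage
boundaries, a JSON manifest (config hash, per-stage wall time, output
checksums) written last.  Stages are deterministic given config + seed
(per-stage seeds fan out from the global seed by stable hashing), so a
resumed run regenerates deleted downstream outputs identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import gainloss as gl
from . import io as oio
from . import simulate as sim
from .config import validate_config
from .mine import mine_genome
from .stats import mann_whitney, pairwise_omega, omega_correlates, repertoire_summary, size_variability
from .trees import DatedSpeciesTree

STAGES = ["simulate", "mine", "classify", "gainloss", "stats"]


def stage_seed(seed: int, stage: str) -> int:
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sim_config(cfg: dict) -> sim.SimConfig:
    tree = (DatedSpeciesTree.from_newick(cfg["tree_newick"]) if cfg["tree_newick"]
            else sim.default_tree())
    per_branch = {}
    if cfg["marine_delta"] is not None:
        per_branch = sim.marine_contrast_rates(tree, (cfg["beta"], cfg["delta"]),
                                               cfg["marine_delta"])
    return sim.SimConfig(
        tree=tree,
        ancestral_family_count=cfg["ancestral_family_count"],
        default_rates=(cfg["beta"], cfg["delta"]),
        per_branch_rates=per_branch,
        genome=sim.GenomeParams(
            contig_count=cfg["contig_count"], contig_length=cfg["contig_length"],
            gc_fraction=cfg["gc_fraction"], decoy_gpcr_count=cfg["decoy_gpcr_count"],
            pseudogenization_fraction=cfg["pseudogenization_fraction"],
            truncation_fraction=cfg["truncation_fraction"],
        ),
        mutation_rate=cfg["mutation_rate"], ogg_divergence=cfg["ogg_divergence"],
        class1_fraction=cfg["class1_fraction"], seed=stage_seed(cfg["seed"], "simulate"),
    )


def run_pipeline(config=None, out_dir="orevo_run", resume: bool = False) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    cfg = validate_config(config)
    out = oio.ensure_dir(out_dir)
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg["seed"], "stages": {}}
    state: dict = {"cfg": cfg}
    for stage in STAGES:
        sdir = oio.ensure_dir(out / stage)
        done = sdir / ".done"
        t0 = time.monotonic()
        try:
            if resume and done.exists():
                _load_stage(stage, sdir, state)
            else:
                globals()[f"_stage_{stage}"](sdir, state)
                done.write_text("ok\n")
        except PipelineError:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(stage, f"missing input: {exc}") from exc
        except Exception as exc:
            raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "files": {p.name: _sha256(p) for p in sorted(sdir.iterdir())
                      if p.is_file() and p.name != ".done"},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(sdir: Path, state: dict) -> None:
    cfg = state["cfg"]
    sc = _sim_config(cfg)
    genomes, truth, reference, content = sim.simulate_run(sc)
    for sp, contigs in genomes.items():
        oio.write_fasta(sdir / f"{sp}.genome.fa", contigs)
    truth.to_tsv(sdir / "truth_genes.tsv", sdir / "truth_events.tsv")
    (sdir / "tree.nwk").write_text(sc.tree.to_newick() + "\n")
    refs = sim.query_references(reference)
    oio.write_fasta(sdir / "queries.fa", {r.id: r.protein for r in refs},
                    {r.id: f"class={r.class_label}" for r in refs})
    oio.write_tm_intervals(sdir / "queries_tm.tsv", refs)
    anchors = sim.class_anchors(reference)
    oio.write_fasta(sdir / "anchors.fa", {k: v[0] for k, v in anchors.items()},
                    {k: f"class={v[1]}" for k, v in anchors.items()})
    oio.write_fasta(sdir / "outgroups.fa", reference.decoy_prototypes)
    pd.DataFrame({"species": sorted(sc.tree.taxa),
                  "habitat": [sim.HABITAT.get(sp, "unknown") for sp in sorted(sc.tree.taxa)]}
                 ).to_csv(sdir / "meta.tsv", sep="\t", index=False)
    state.update(genomes=genomes, truth=truth, reference=reference, content=content,
                 sim_config=sc, queries=refs, anchors=anchors,
                 outgroups=dict(reference.decoy_prototypes),
                 tree=sc.tree, meta={sp: sim.HABITAT.get(sp, "unknown") for sp in sc.tree.taxa})


def _stage_mine(sdir: Path, state: dict) -> None:
    cfg = state["cfg"]
    mine_cfg = {k: cfg[k] for k in ("derep_identity", "evalue1", "evalue2",
                                    "min_protein_length", "tm_gap_max", "nterm_min",
                                    "nterm_max", "contig_end_max_bp", "region_join_bp")}
    all_calls = []
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    for sp in sorted(state["genomes"]):
        genome = state["genomes"][sp]
        calls = mine_genome(genome, state["queries"], state["outgroups"], species=sp,
                            config=mine_cfg)
        for c in calls:
            if c.protein:
                proteins[c.gene_id] = c.protein
            if c.status == "intact":
                seq = genome[c.contig][c.start:c.end]
                if c.strand == "-":
                    from .sequences import reverse_complement
                    seq = reverse_complement(seq)
                cds[c.gene_id] = seq[:-3]  # strip the stop codon
        all_calls.extend(calls)
    oio.write_calls(sdir / "calls.tsv", all_calls)
    oio.write_fasta(sdir / "intact_proteins.fa",
                    {c.gene_id: c.protein for c in all_calls if c.status == "intact"})
    oio.write_fasta(sdir / "nonintact_proteins.fa",
                    {c.gene_id: c.protein for c in all_calls
                     if c.status != "intact" and c.protein})
    oio.write_fasta(sdir / "intact_cds.fa", cds)
    state.update(calls=all_calls, mined_proteins=proteins, intact_cds=cds)


def _stage_classify(sdir: Path, state: dict) -> None:
    cfg = state["cfg"]
    calls = state["calls"]
    intact = {c.gene_id: c.protein for c in calls if c.status == "intact"}
    nonintact = {c.gene_id: c.protein for c in calls if c.status != "intact" and c.protein}
    status = {c.gene_id: c.status for c in calls}
    species_of = {c.gene_id: c.species for c in calls}
    oggs, table = clf.classify_repertoire(
        intact, species_of, state["anchors"], nonintact=nonintact,
        nonintact_status=status, outgroup_gpcrs=state["outgroups"],
        support_floor=cfg["support_floor"], replicates=min(cfg["bootstrap_replicates"], 200),
        inflation=cfg["mcl_inflation"], seed=stage_seed(cfg["seed"], "classify"),
    )
    table.to_csv(sdir / "oggs.tsv", sep="\t", index=False)
    state.update(oggs=oggs, ogg_table=table)


def _stage_gainloss(sdir: Path, state: dict) -> None:
    cfg = state["cfg"]
    if "tree" not in state or state["tree"] is None:
        raise PipelineError("gainloss", "preflight: no dated species tree available")
    model = gl.GeneContentModel.from_ogg_table(state["ogg_table"], state["tree"],
                                               count_mode=cfg["count_mode"])
    res = model.fit()
    res.content.to_csv(sdir / "content.tsv", sep="\t")
    res.events_frame.to_csv(sdir / "events.tsv", sep="\t")
    res.rates_frame.to_csv(sdir / "rates.tsv", sep="\t")
    groups = {sp: h for sp, h in state["meta"].items() if h in ("marine", "terrestrial")}
    res.group_means(groups).to_csv(sdir / "group_rates.tsv", sep="\t")
    state.update(gainloss=res)


def _stage_stats(sdir: Path, state: dict) -> None:
    calls_df = pd.DataFrame([{"species": c.species, "status": c.status}
                             for c in state["calls"]])
    summary = repertoire_summary(calls_df, habitat=state["meta"], ogg_table=state["ogg_table"])
    summary.to_csv(sdir / "species_summary.tsv", sep="\t")
    species = sorted(state["tree"].taxa)
    var_frame, (r, p) = size_variability(state["ogg_table"], species)
    var_frame.to_csv(sdir / "ogg_variability.tsv", sep="\t")
    report: dict = {"sd_vs_total": {"r": r, "p": p}}
    marine = summary[summary.get("habitat") == "marine"]["intact"]
    terr = summary[summary.get("habitat") == "terrestrial"]["intact"]
    if len(marine) and len(terr):
        U, pv = mann_whitney(marine, terr)
        report["marine_vs_terrestrial_intact"] = {"U": U, "p": pv,
                                                  "n": [int(len(marine)), int(len(terr))]}
    # NG86 omega per OGG on intact CDS (3+ members)
    tab = state["ogg_table"]
    intact_tab = tab[tab["status"] == "intact"]
    omegas = []
    cds = state.get("intact_cds", {})
    for ogg_name, grp in intact_tab.groupby("ogg_name"):
        seqs = {g: cds[g] for g in grp["gene_id"] if g in cds}
        seqs = {g: s for g, s in seqs.items()
                if len(s) == len(next(iter(seqs.values()), ""))}
        if len(seqs) >= 3:
            est = pairwise_omega(ogg_name, seqs)
            omegas.append({"ogg": est.ogg, "omega": est.omega,
                           "n_pairs": est.n_pairs, "flag": est.flag})
    omega_df = pd.DataFrame(omegas, columns=["ogg", "omega", "n_pairs", "flag"])
    omega_df.to_csv(sdir / "omega.tsv", sep="\t", index=False)
    if len(omega_df.dropna(subset=["omega"])) >= 3 and "gainloss" in state:
        events = gl.per_ogg_events(state["gainloss"].content, state["tree"])
        try:
            report["omega_correlates"] = _jsonable(
                omega_correlates(omega_df, tab, events))
        except ValueError as exc:
            report["omega_correlates"] = {"flag": str(exc)}
    (sdir / "tests.json").write_text(json.dumps(report, indent=2, default=float))
    state.update(stats_report=report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# resume support: reload a completed stage's outputs
# ---------------------------------------------------------------------------

def _load_stage(stage: str, sdir: Path, state: dict) -> None:
    if stage == "simulate":
        genomes = {}
        for fa in sorted(sdir.glob("*.genome.fa")):
            sp = fa.name.replace(".genome.fa", "")
            genomes[sp] = oio.read_fasta(fa)
        tree = DatedSpeciesTree.from_file(sdir / "tree.nwk")
        meta_df = pd.read_csv(sdir / "meta.tsv", sep="\t")
        state.update(
            genomes=genomes, tree=tree,
            queries=oio.load_references(sdir / "queries.fa", sdir / "queries_tm.tsv"),
            anchors=oio.load_labeled_proteins(sdir / "anchors.fa"),
            outgroups=oio.read_fasta(sdir / "outgroups.fa"),
            meta=dict(zip(meta_df["species"], meta_df["habitat"])),
        )
    elif stage == "mine":
        df = oio.read_calls(sdir / "calls.tsv")
        from .mine import ORGeneCall
        prots = {**oio.read_fasta(sdir / "intact_proteins.fa"),
                 **oio.read_fasta(sdir / "nonintact_proteins.fa")}
        calls = []
        for row in df.itertuples():
            calls.append(ORGeneCall(
                gene_id=row.gene_id, species=row.species, contig=row.contig,
                strand=row.strand, start=int(row.start) - 1, end=int(row.end),
                status=row.status, protein=prots.get(row.gene_id, ""),
                disruptions=[d for d in str(row.disruptions).split(";") if d],
                flags={"pseudogene": bool(row.pseudogene_flag),
                       "truncated": bool(row.truncated_flag)},
            ))
        state.update(calls=calls, intact_cds=oio.read_fasta(sdir / "intact_cds.fa"))
    elif stage == "classify":
        state.update(ogg_table=pd.read_csv(sdir / "oggs.tsv", sep="\t"))
    elif stage == "gainloss":
        model = gl.GeneContentModel.from_ogg_table(state["ogg_table"], state["tree"],
                                                   count_mode=state["cfg"]["count_mode"])
        state.update(gainloss=model.fit())
    elif stage == "stats":
        state.update(stats_report=json.loads((sdir / "tests.json").read_text()))
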