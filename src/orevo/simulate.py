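"""Ground-truthed synthetic inputs for the OR repertoire pipeline.

The generator emulates the study system end to end: a dated mammal tree
(11 marine + 11 terrestrial species + an outgroup), an ancestral repertoire
of orthologous gene groups (OGGs) evolving by per-branch gain (beta) and
loss (delta) rates, and per-species genome FASTA files carrying each
surviving gene as an intronless ATG..stop ORF, with configurable fractions
disabled (premature stop / frameshift), truncated at contig ends, plus
decoy non-OR GPCR genes.

Gains and losses are drawn as a Gillespie process with per-gene event
intensities beta and delta, so the realized mean behaviour matches the
deterministic model dg/dt = (A0 + g - l) beta used by the rate estimator.

OR architecture: ~300-aa proteins with seven transmembrane (TM) helices on
a fixed template grid (hydrophobic-biased TM residues), N-terminal segment
of 26 aa (inside the miner's accepted 21-34 aa window).  Proteins are
back-translated with random synonymous codons; substitutions along the
tree are uniform (Jukes-Cantor-like) with no indels in intact genes, so
planted intact genes always satisfy the miner's intactness definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sequences import CODON_TO_AA, STOP_CODONS
from .trees import DatedSpeciesTree

# ---------------------------------------------------------------------------
# default study system: 23 taxa, TimeTree-like ages (MY)
# ---------------------------------------------------------------------------

DEFAULT_TREE_NEWICK = (
    "(opossum,(((alpaca,(pig,((cattle,goat)24,((minke_whale,bowhead_whale)28,"
    "(sperm_whale,(baiji,(beluga,(killer_whale,bottlenose_dolphin)10)19)27)33)34)56)62)64,"
    "(horse,(dog,(panda,(ferret,(walrus,(weddell_seal,monk_seal)12)24)38)43)46)74)78,"
    "((elephant,manatee)60,(golden_mole,elephant_shrew)71)79)99)159;"
)

MARINE_SPECIES = (
    "killer_whale", "sperm_whale", "minke_whale", "bowhead_whale", "beluga",
    "bottlenose_dolphin", "baiji", "weddell_seal", "monk_seal", "walrus", "manatee",
)
TERRESTRIAL_SPECIES = (
    "cattle", "pig", "goat", "alpaca", "ferret", "panda", "dog", "horse",
    "golden_mole", "elephant_shrew", "elephant",
)
OUTGROUP_SPECIES = ("opossum",)

HABITAT = {sp: "marine" for sp in MARINE_SPECIES}
HABITAT.update({sp: "terrestrial" for sp in TERRESTRIAL_SPECIES})
HABITAT.update({sp: "outgroup" for sp in OUTGROUP_SPECIES})


def default_tree() -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick(DEFAULT_TREE_NEWICK)


# ---------------------------------------------------------------------------
# protein architecture
# ---------------------------------------------------------------------------

N_TERM = 26
TM_LEN = 23
LOOP_LEN = 15
C_TERM = 24
TM_INTERVALS: list[tuple[int, int]] = [
    (N_TERM + i * (TM_LEN + LOOP_LEN), N_TERM + i * (TM_LEN + LOOP_LEN) + TM_LEN)
    for i in range(7)
]
PROTEIN_LEN = TM_INTERVALS[-1][1] + C_TERM  # 301 aa

HYDROPHOBIC = "AILMFVWCGT"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"

_TM_MASK = np.zeros(PROTEIN_LEN, dtype=bool)
for _s, _e in TM_INTERVALS:
    _TM_MASK[_s:_e] = True

_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _SYN_CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(STOP_CODONS)


def random_protein(rng: np.random.Generator) -> str:
    """A fresh template protein on the fixed 7-TM grid, starting with Met."""
    res = [
        HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))] if _TM_MASK[i]
        else ALL_AA[rng.integers(len(ALL_AA))]
        for i in range(PROTEIN_LEN)
    ]
    res[0] = "M"
    return "".join(res)


def derive_protein(template: str, divergence: float, rng: np.random.Generator) -> str:
    """Mutate a fraction of residues, keeping TM positions hydrophobic."""
    res = list(template)
    for i in range(1, len(res)):
        if rng.random() < divergence:
            pool = HYDROPHOBIC if _TM_MASK[i] else ALL_AA
            new = pool[rng.integers(len(pool))]
            res[i] = new
    return "".join(res)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codons; appends a random stop codon."""
    codons = [_SYN_CODONS[aa][rng.integers(len(_SYN_CODONS[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


_BASES = "ACGT"


def mutate_dna(dna: str, n_subs: int, rng: np.random.Generator, keep_orf: bool = True,
               max_tries: int = 50) -> str:
    """Apply uniform point substitutions.  With ``keep_orf`` the start
    codon, terminal stop and absence of internal stops are preserved
    (a disallowed draw is resampled)."""
    seq = list(dna)
    n = len(seq)
    for _ in range(n_subs):
        for _try in range(max_tries):
            pos = int(rng.integers(n))
            old = seq[pos]
            new = _BASES[int(rng.integers(4))]
            if new == old:
                continue
            if keep_orf:
                if pos < 3 or pos >= n - 3:
                    continue
                cstart = pos - pos % 3
                codon = "".join(seq[cstart : cstart + 3])
                mutated = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
                if mutated in STOP_CODONS:
                    continue
            seq[pos] = new
            break
    return "".join(seq)


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeParams:
    contig_count: int = 24
    contig_length: int = 30_000
    gc_fraction: float = 0.42
    decoy_gpcr_count: int = 5
    pseudogenization_fraction: float = 0.25
    truncation_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.pseudogenization_fraction + self.truncation_fraction > 1:
            raise ValueError("pseudogenization + truncation fractions must be <= 1")


@dataclass
class SimConfig:
    """Study conditions for a synthetic run.

    ``per_branch_rates`` maps branch keys (child node keys of the tree;
    see DatedSpeciesTree.node_key) to (beta, delta) in gains/losses per
    gene per MY; branches not listed use ``default_rates``.  The default
    repertoire size and rates mirror the study regime: 830 ancestral
    OGGs, terrestrial-like beta = delta = 0.003.
    """

    tree: DatedSpeciesTree = field(default_factory=default_tree)
    ancestral_family_count: int = 830
    default_rates: tuple[float, float] = (0.003, 0.003)
    per_branch_rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    genome: GenomeParams = field(default_factory=GenomeParams)
    mutation_rate: float = 0.0005  # substitutions per nt site per MY
    duplication_divergence_my: float = 4.0  # extra MY of divergence per additional copy in an OGG
    ogg_divergence: float = 0.35  # protein divergence of each OGG prototype from its class template
    class1_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestral_family_count <= 0:
            raise ValueError("ancestral_family_count must be positive")
        for key, (b, d) in self.per_branch_rates.items():
            if b < 0 or d < 0:
                raise ValueError(f"negative rate on branch {key}")
        if min(self.default_rates) < 0:
            raise ValueError("negative default rate")

    def rates_for(self, branch_key: str) -> tuple[float, float]:
        return self.per_branch_rates.get(branch_key, self.default_rates)


def marine_contrast_rates(tree: DatedSpeciesTree,
                          terrestrial: tuple[float, float] = (0.003, 0.003),
                          marine_delta: float = 0.017) -> dict[str, tuple[float, float]]:
    """Per-branch rate map with elevated loss on marine terminal branches."""
    rates = {}
    for nd in tree.tree.leaf_node_iter():
        sp = nd.taxon.label
        if HABITAT.get(sp) == "marine":
            rates[sp] = (terrestrial[0], marine_delta)
    return rates


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth of a synthetic run: planted genes and true per-branch
    event counts."""

    genes: pd.DataFrame  # species, gene_id, ogg_id, status, contig, start, end, strand
    branch_events: pd.DataFrame  # branch, G_true, L_true

    def to_tsv(self, genes_path, events_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index=False)
        self.branch_events.to_csv(events_path, sep="\t", index=False)


def simulate_family_evolution(config: SimConfig, rng: np.random.Generator | None = None
                              ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Evolve per-OGG copy numbers down the tree.

    Returns (content, branch_events): ``content`` maps node keys to
    integer copy-number vectors over the ancestral OGGs; ``branch_events``
    records true G and L per branch (keyed by child node).

    Events are drawn per branch as a Gillespie process: with N current
    genes the next event occurs after an Exp(N (beta+delta)) wait and is a
    gain with probability beta/(beta+delta); the affected gene is chosen
    uniformly, so duplications accrue within existing OGGs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = config.tree
    root = tree.tree.seed_node
    n_ogg = config.ancestral_family_count
    content: dict[str, np.ndarray] = {tree.node_key(root): np.ones(n_ogg, dtype=int)}
    per_ogg: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        key = tree.node_key(nd)
        beta, delta = config.rates_for(key)
        state = content[tree.node_key(nd.parent_node)].copy()
        T = tree.branch_duration(nd)
        gains_vec = np.zeros(n_ogg, dtype=int)
        losses_vec = np.zeros(n_ogg, dtype=int)
        t = 0.0
        total_rate = beta + delta
        while total_rate > 0:
            N = int(state.sum())
            if N == 0:
                break
            t += rng.exponential(1.0 / (N * total_rate))
            if t >= T:
                break
            # pick a gene uniformly: OGG index weighted by copy number
            g = int(rng.integers(N))
            ogg = int(np.searchsorted(np.cumsum(state), g, side="right"))
            if rng.random() < beta / total_rate:
                state[ogg] += 1
                gains_vec[ogg] += 1
            else:
                state[ogg] -= 1
                losses_vec[ogg] += 1
        content[key] = state
        per_ogg[key] = (gains_vec, losses_vec)
        rows.append({"branch": key, "G_true": int(gains_vec.sum()),
                     "L_true": int(losses_vec.sum()),
                     "beta_true": beta, "delta_true": delta, "T": T})
    events = pd.DataFrame(rows)
    events.attrs["per_ogg"] = per_ogg
    return content, events


# ---------------------------------------------------------------------------
# genome emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticReference:
    """Class templates, per-OGG prototypes and decoy (non-OR GPCR)
    prototypes underlying one synthetic run."""

    class_templates: dict[str, str]  # "I" / "II" -> protein
    ogg_prototypes: dict[str, str]  # ogg id -> protein
    ogg_class: dict[str, str]
    ogg_dna: dict[str, str]  # ogg id -> prototype CDS (ATG..stop)
    decoy_prototypes: dict[str, str]  # decoy id -> protein
    decoy_dna: dict[str, str]

    @property
    def tm_intervals(self) -> list[tuple[int, int]]:
        return list(TM_INTERVALS)


def build_reference(config: SimConfig, rng: np.random.Generator) -> SyntheticReference:
    templates = {"I": random_protein(rng), "II": random_protein(rng)}
    n = config.ancestral_family_count
    n_class1 = max(1, int(round(config.class1_fraction * n))) if n > 1 else 1
    ogg_prototypes, ogg_class, ogg_dna = {}, {}, {}
    for i in range(n):
        cls = "I" if i < n_class1 else "II"
        ogg_id = f"ogg{i:04d}"
        prot = derive_protein(templates[cls], config.ogg_divergence, rng)
        ogg_prototypes[ogg_id] = prot
        ogg_class[ogg_id] = cls
        ogg_dna[ogg_id] = back_translate(prot, rng)
    decoy_prototypes, decoy_dna = {}, {}
    for i in range(config.genome.decoy_gpcr_count):
        did = f"gpcr{i:02d}"
        # decoys share the OR fold scaffold but form their own sequence
        # neighbourhood, mimicking non-OR rhodopsin-family GPCRs
        prot = derive_protein(templates["II"], min(0.55, config.ogg_divergence + 0.2), rng)
        decoy_prototypes[did] = prot
        decoy_dna[did] = back_translate(prot, rng)
    return SyntheticReference(templates, ogg_prototypes, ogg_class, ogg_dna,
                              decoy_prototypes, decoy_dna)


def _root_to_tip_my(tree: DatedSpeciesTree) -> float:
    return tree.tree.seed_node.age_my


def _place_gene(contig: list[str], gene: str, occupied: list[tuple[int, int]],
                rng: np.random.Generator, at_end: str | None = None,
                margin: int = 80, spacing: int = 150,
                max_attempts: int = 200) -> tuple[int, int]:
    """Insert ``gene`` into the contig (list of chars), non-overlapping.

    Interior placements keep ``margin`` bp clear of contig boundaries (so
    only deliberately truncated copies trigger the miner's contig-end
    rule) and ``spacing`` bp between genes (so neighbouring loci are never
    merged into one matched region).  ``at_end`` in {'left','right'} pins
    the gene flush to a contig boundary for truncated copies.
    """
    L = len(contig)
    gl = len(gene)
    if gl + 2 * margin > L and at_end is None:
        raise ValueError("contig too short for gene")
    for _ in range(max_attempts):
        if at_end == "left":
            start = 0
        elif at_end == "right":
            start = L - gl
        else:
            start = int(rng.integers(margin, L - gl - margin + 1))
        end = start + gl
        if all(end + spacing <= s or start >= e + spacing for s, e in occupied):
            contig[start:end] = list(gene)
            occupied.append((start, end))
            return start, end
        if at_end:
            break
    raise RuntimeError("could not place gene after bounded attempts")


def _sanitize_upstream_starts(contig: list[str], start: int, end: int, strand: str,
                              n_codons: int = 9) -> None:
    """Rewrite in-frame ATG codons in the flank just upstream of a planted
    start so the miner's longest-qualifying-N-terminus rule lands on the
    planted start codon rather than a random flank ATG."""
    if strand == "+":
        for k in range(1, n_codons + 1):
            a = start - 3 * k
            if a < 0:
                break
            if contig[a] == "A" and contig[a + 1] == "T" and contig[a + 2] == "G":
                contig[a + 1] = "C"
    else:
        for k in range(1, n_codons + 1):
            a = end + 3 * (k - 1)
            if a + 3 > len(contig):
                break
            # gene-orientation ATG reads CAT on the forward strand
            if contig[a] == "C" and contig[a + 1] == "A" and contig[a + 2] == "T":
                contig[a + 1] = "G"


def _pseudogenize(dna: str, rng: np.random.Generator) -> str:
    """Disable an ORF with a premature stop or a 1-2 bp frameshift."""
    n_codons = len(dna) // 3 - 1
    if rng.random() < 0.5:
        # nonsense mutation somewhere in the middle third
        c = int(rng.integers(n_codons // 3, 2 * n_codons // 3))
        stop = _STOPS[int(rng.integers(3))]
        return dna[: 3 * c] + stop + dna[3 * c + 3 :]
    k = int(rng.integers(1, 3))
    pos = int(rng.integers(len(dna) // 3, 2 * len(dna) // 3))
    return dna[:pos] + dna[pos + k :]


def emit_genomes(content: dict[str, np.ndarray], config: SimConfig,
                 reference: SyntheticReference | None = None,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[dict[str, dict[str, str]], pd.DataFrame, SyntheticReference]:
    """Materialise tip repertoires as genome FASTA dictionaries.

    Returns (genomes, truth, reference) where genomes maps
    species -> {contig name -> sequence}.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if reference is None:
        reference = build_reference(config, rng)
    tree = config.tree
    gp = config.genome
    depth = _root_to_tip_my(tree)
    genomes: dict[str, dict[str, str]] = {}
    rows = []
    ogg_ids = sorted(reference.ogg_prototypes)
    for leaf in sorted(tree.tree.leaf_node_iter(), key=lambda n: n.taxon.label):
        sp = leaf.taxon.label
        counts = content[sp]
        contigs = [list(random_background(gp.contig_length, gp.gc_fraction, rng))
                   for _ in range(gp.contig_count)]
        occupied: list[list[tuple[int, int]]] = [[] for _ in range(gp.contig_count)]
        gene_no = 0
        plan: list[tuple[str, str, str]] = []  # (gene_id, ogg_id, status)
        for ogg_idx, k in enumerate(counts):
            ogg_id = ogg_ids[ogg_idx]
            for copy_idx in range(int(k)):
                u = rng.random()
                if u < gp.pseudogenization_fraction:
                    status = "pseudogene"
                elif u < gp.pseudogenization_fraction + gp.truncation_fraction:
                    status = "truncated"
                else:
                    status = "intact"
                plan.append((f"{sp}_or{gene_no:04d}", ogg_id, status, copy_idx))
                gene_no += 1
        for i in range(gp.decoy_gpcr_count):
            did = sorted(reference.decoy_prototypes)[i]
            plan.append((f"{sp}_decoy{i:02d}", did, "decoy", 0))

        for gene_id, origin, status, copy_idx in plan:
            base_dna = reference.ogg_dna.get(origin, reference.decoy_dna.get(origin))
            # later copies in an expanded OGG carry extra divergence,
            # standing in for their longer duplication history
            my = depth + config.duplication_divergence_my * copy_idx
            sub_prob = 1.0 - np.exp(-config.mutation_rate * my)
            n_subs = int(rng.binomial(len(base_dna), sub_prob))
            dna = mutate_dna(base_dna, n_subs, rng, keep_orf=True)
            strand = "+" if rng.random() < 0.5 else "-"
            at_end = None
            if status == "pseudogene":
                dna = _pseudogenize(dna, rng)
            elif status == "truncated":
                # disruption-free fragment cut by the contig boundary
                keep = int(rng.integers(120, len(dna) // 3 - 5)) * 3
                if rng.random() < 0.5:
                    dna = dna[:keep]  # 3' lost -> pin downstream end to boundary
                    at_end = "right" if strand == "+" else "left"
                else:
                    dna = dna[-keep:]  # 5' lost
                    at_end = "left" if strand == "+" else "right"
            placed = dna if strand == "+" else _revcomp(dna)
            ci = int(rng.integers(gp.contig_count))
            for attempt in range(gp.contig_count):
                try:
                    idx = (ci + attempt) % gp.contig_count
                    start, end = _place_gene(contigs[idx], placed, occupied[idx], rng,
                                             at_end=at_end)
                    break
                except RuntimeError:
                    continue
            else:
                raise RuntimeError(f"could not place {gene_id} on any contig")
            if status in ("intact", "decoy"):
                _sanitize_upstream_starts(contigs[idx], start, end, strand)
            rows.append({
                "species": sp, "gene_id": gene_id, "ogg_id": origin, "status": status,
                "contig": f"{sp}_contig{idx:03d}", "start": start, "end": end,
                "strand": strand,
            })
        genomes[sp] = {f"{sp}_contig{i:03d}": "".join(c) for i, c in enumerate(contigs)}
    truth_genes = pd.DataFrame(rows, columns=["species", "gene_id", "ogg_id", "status",
                                              "contig", "start", "end", "strand"])
    return genomes, truth_genes, reference


def _revcomp(s: str) -> str:
    from .sequences import reverse_complement
    return reverse_complement(s)


def query_references(reference: SyntheticReference, per_class: int = 3):
    """Reference OR query set for the miner: the two class templates plus
    the first ``per_class`` OGG prototypes of each class, all with the
    shared TM annotation (dereplication happens in the miner)."""
    from .mine import ReferenceOR

    refs = [ReferenceOR(f"template_{cls}", prot, cls, list(TM_INTERVALS))
            for cls, prot in sorted(reference.class_templates.items())]
    taken = {"I": 0, "II": 0}
    for ogg_id in sorted(reference.ogg_prototypes):
        cls = reference.ogg_class[ogg_id]
        if taken[cls] >= per_class:
            continue
        taken[cls] += 1
        refs.append(ReferenceOR(f"query_{ogg_id}", reference.ogg_prototypes[ogg_id],
                                cls, list(TM_INTERVALS)))
    return refs


def class_anchors(reference: SyntheticReference) -> dict[str, tuple[str, str]]:
    """Labeled Class I/II anchor proteins for the classifier."""
    return {f"anchor_{cls}": (prot, cls)
            for cls, prot in sorted(reference.class_templates.items())}


def simulate_run(config: SimConfig) -> tuple[dict[str, dict[str, str]], TruthTable, SyntheticReference, dict[str, np.ndarray]]:
    """Full synthetic run: family evolution + genome emission.

    Deterministic for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    content, branch_events = simulate_family_evolution(config, rng)
    genomes, truth_genes, reference = emit_genomes(content, config, rng=rng)
    truth = TruthTable(genes=truth_genes, branch_events=branch_events)
    return genomes, truth, reference, content
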