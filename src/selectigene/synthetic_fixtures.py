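"""Synthetic microbiome generation with controllable design signal.

The generator emulates the structure the design pipeline consumes from
real annotated genomes: per-host proteomes whose codon usage is skewed
by role (wanted hosts draw codons from preference vectors P_A, unwanted
hosts from P_B, with the distance between them scaled by
``bias_strength``), 200-bp promoters with an optional planted motif in
the strong promoters of wanted hosts, intergenic spacers, tGCN tables
and ribosome-density tables consistent with the codon preferences,
Poisson-sized restriction-enzyme repertoires drawn from a shared pool,
and 16S sequences. Everything is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import (AA_TO_CODONS, CODON_INDEX, SENSE_CODONS,
                     reverse_complement)
from .sequence_model import (GeneRecord, HostGenome, Microbiome,
                             extract_regions)

AA_LIST = tuple(sorted(AA_TO_CODONS))
_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of one synthetic microbiome."""

    seed: int
    n_wanted: int = 3
    n_unwanted: int = 3
    genes_per_host: int = 50
    gene_length_codons: int = 200
    bias_strength: float = 0.7
    planted_motif: str | None = None
    n_decoy_motifs: int = 3
    decoy_fraction: float = 0.5
    motif_fraction: float = 0.7
    enzyme_pool_size: int = 30
    sites_per_host: float = 4.6
    disjoint_enzymes: bool = False

    def __post_init__(self) -> None:
        for name in ("n_wanted", "n_unwanted", "genes_per_host",
                     "gene_length_codons", "enzyme_pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.bias_strength <= 1:
            raise ValueError("bias_strength must be in [0, 1]")


# ---------------------------------------------------------------------------
# codon preferences


def contrast_preferences(rng: np.random.Generator, bias_strength: float,
                         ) -> tuple[dict[str, float], dict[str, float]]:
    """(P_A, P_B): per-codon preference maps whose within-family contrast
    scales with *bias_strength* (0 = identical, 1 = fully mirrored)."""
    pa, pb = {}, {}
    for aa in AA_LIST:
        codons = AA_TO_CODONS[aa]
        x = rng.dirichlet(np.ones(len(codons)))
        y = (1 - bias_strength) * x + bias_strength * x[::-1]
        for c, va, vb in zip(codons, x, y):
            pa[c] = float(va)
            pb[c] = float(vb)
    return pa, pb


def relative_preference(pref: dict[str, float]) -> dict[str, float]:
    """Preference rescaled to its within-family maximum (CAI-comparable)."""
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        fmax = max(pref[c] for c in codons)
        for c in codons:
            out[c] = pref[c] / fmax
    return out


def _jitter(pref: dict[str, float], rng: np.random.Generator,
            scale: float = 0.02) -> dict[str, float]:
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        v = np.array([pref[c] for c in codons])
        v = v + scale * rng.dirichlet(np.ones(len(codons)))
        v = v / v.sum()
        for c, p in zip(codons, v):
            out[c] = float(p)
    return out


def _sample_codon(aa: str, pref: dict[str, float],
                  rng: np.random.Generator) -> str:
    codons = AA_TO_CODONS[aa]
    p = np.array([pref[c] for c in codons])
    return codons[int(rng.choice(len(codons), p=p / p.sum()))]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _instantiate_iupac(motif: str, rng: np.random.Generator) -> str:
    from .codons import IUPAC_SETS
    return "".join(ch if ch in "ACGT"
                   else sorted(IUPAC_SETS[ch])[int(rng.integers(len(IUPAC_SETS[ch])))]
                   for ch in motif)


# ---------------------------------------------------------------------------
# enzyme pool


def _enzyme_pool(rng: np.random.Generator, size: int) -> list[str]:
    """A pool of 6-bp recognition sites: palindromes, non-palindromes,
    and a few with one IUPAC ambiguity."""
    pool: list[str] = []
    seen = set()
    attempt = 0
    while len(pool) < size:
        # cycle by attempt, not pool size: only 64 palindromic 6-mers
        # exist, so large pools must fall through to the other kinds
        kind = attempt % 3
        attempt += 1
        if kind == 0:
            half = _random_dna(rng, 3)
            site = half + reverse_complement(half)
        elif kind == 1:
            site = _random_dna(rng, 6)
        else:
            site = list(_random_dna(rng, 6))
            site[int(rng.integers(1, 5))] = "RYWS"[int(rng.integers(4))]
            site = "".join(site)
        if site not in seen:
            seen.add(site)
            pool.append(site)
    return pool


# ---------------------------------------------------------------------------
# host construction


GAP = 250          # bp between genes: 200-bp promoter + 50-bp intergenic
RRNA_LEN = 600


def _build_host(host_id: str, role: str, pref: dict[str, float],
                spec: FixtureSpec, rng: np.random.Generator,
                pool: list[str], rrna_root: str) -> HostGenome:
    genes: list[GeneRecord] = []
    parts: list[str] = []
    pos = 0
    n_aa = spec.gene_length_codons - 1
    for j in range(spec.genes_per_host):
        spacer = _random_dna(rng, GAP)
        aa_seq = "M" + "".join(AA_LIST[i] for i in
                               rng.integers(0, len(AA_LIST), size=n_aa - 1))
        cds = "ATG" + "".join(_sample_codon(a, pref, rng)
                              for a in aa_seq[1:]) + "TAA"
        parts.append(spacer)
        pos += GAP
        start = pos
        parts.append(cds)
        pos += len(cds)
        expression = float(rng.lognormal(0.0, 1.0))
        genes.append(GeneRecord(gene_id=f"{host_id}_g{j:03d}", cds_seq=cds,
                                strand="+", contig_id="chr1", start=start,
                                end=pos, expression=expression))
    parts.append(_random_dna(rng, GAP))
    contig = "".join(parts)

    # plant motifs into the strong (top-tertile) promoters of wanted hosts:
    # the shared motif goes into the 5' half of the promoter, host-private
    # decoy motifs into the 3' half (real promoter sets carry many motifs
    # beyond any shared one, which spreads the aggregated motif scores)
    if role == "wanted" and spec.planted_motif:
        order = sorted(genes, key=lambda g: (-g.expression, g.gene_id))
        strong = order[:max(1, len(genes) // 3)]
        n_plant = max(1, int(round(spec.motif_fraction * len(strong))))
        chars = list(contig)
        perm = [strong[i] for i in rng.permutation(len(strong))]
        for g in perm[:n_plant]:
            inst = _instantiate_iupac(spec.planted_motif, rng)
            off = int(rng.integers(10, 90 - len(inst)))
            p0 = g.start - 200 + off
            chars[p0:p0 + len(inst)] = inst
        for _ in range(spec.n_decoy_motifs):
            decoy = _random_dna(rng, 8)
            n_decoy = max(1, int(round(spec.decoy_fraction * len(strong))))
            perm = [strong[i] for i in rng.permutation(len(strong))]
            for g in perm[:n_decoy]:
                off = int(rng.integers(100, 200 - len(decoy) - 5))
                p0 = g.start - 200 + off
                chars[p0:p0 + len(decoy)] = decoy
        contig = "".join(chars)

    # tGCN and ribo-density consistent with the codon preferences
    tgcn = {reverse_complement(c): int(1 + round(9 * relative_preference(pref)[c]))
            for c in SENSE_CODONS}
    tdr = {c: 1.0 / (0.1 + relative_preference(pref)[c]) for c in SENSE_CODONS}

    if spec.disjoint_enzymes:
        half = len(pool) // 2
        sub = pool[:half] if role == "wanted" else pool[half:]
    else:
        sub = pool
    n_enz = min(len(sub), max(1, int(rng.poisson(spec.sites_per_host))))
    enzymes = [sub[i] for i in
               sorted(rng.choice(len(sub), size=n_enz, replace=False))]

    rrna = list(rrna_root)
    n_mut = int(rng.poisson(20))
    for p in rng.choice(RRNA_LEN, size=min(n_mut, RRNA_LEN), replace=False):
        cur = rrna[p]
        rrna[p] = sorted(set("ACGT") - {cur})[int(rng.integers(3))]

    host = HostGenome(host_id=host_id, role=role, genes=genes,
                      contigs={"chr1": contig}, tgcn=tgcn, tdr=tdr,
                      enzymes=enzymes, rrna_16s="".join(rrna))
    extract_regions(host)
    return host


def make_microbiome(spec: FixtureSpec) -> Microbiome:
    """Generate a full synthetic microbiome from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    pa, pb = contrast_preferences(rng, spec.bias_strength)
    pool = _enzyme_pool(rng, spec.enzyme_pool_size)
    rrna_root = _random_dna(rng, RRNA_LEN)
    hosts = []
    for i in range(spec.n_wanted):
        hosts.append(_build_host(f"wanted{i}", "wanted", _jitter(pa, rng),
                                 spec, rng, pool, rrna_root))
    for i in range(spec.n_unwanted):
        hosts.append(_build_host(f"unwanted{i}", "unwanted", _jitter(pb, rng),
                                 spec, rng, pool, rrna_root))
    return Microbiome(hosts=hosts)


def make_goi(length_codons: int, seed: int) -> GeneRecord:
    """A random gene of interest: uniform-codon back-translation of a
    random protein, with start and stop codons and no internal stop."""
    if length_codons < 10:
        raise ValueError("GOI length must be >= 10 codons")
    rng = np.random.default_rng(seed)
    aa_seq = "M" + "".join(AA_LIST[i] for i in
                           rng.integers(0, len(AA_LIST), size=length_codons - 1))
    codons = ["ATG"]
    for a in aa_seq[1:]:
        fam = AA_TO_CODONS[a]
        codons.append(fam[int(rng.integers(len(fam)))])
    codons.append("TAA")
    return GeneRecord(gene_id=f"goi_seed{seed}", cds_seq="".join(codons))


# ---------------------------------------------------------------------------
# graded pool for phylogenetic-resolution experiments


def make_gradient_pool(n_hosts: int, seed: int, genes_per_host: int = 30,
                       gene_length_codons: int = 150) -> Microbiome:
    """Hosts along a codon-preference gradient whose 16S divergence is
    proportional to their preference contrast.

    Host *i* sits at position ``t_i = i / (n - 1)`` between two mirrored
    preference vectors, and mutates the first ``round(150 * t_i)``
    positions of a shared mutation schedule of its 16S, so the pairwise
    16S difference count is proportional to ``|t_i - t_j|``.
    """
    if n_hosts < 2:
        raise ValueError("pool needs >= 2 hosts")
    rng = np.random.default_rng(seed)
    pa, pb = contrast_preferences(rng, 1.0)
    pool = _enzyme_pool(rng, 20)
    rrna_root = _random_dna(rng, RRNA_LEN)
    schedule = rng.permutation(RRNA_LEN)
    hosts = []
    spec = FixtureSpec(seed=seed, genes_per_host=genes_per_host,
                       gene_length_codons=gene_length_codons)
    for i in range(n_hosts):
        t = i / (n_hosts - 1)
        pref = {c: (1 - t) * pa[c] + t * pb[c] for c in SENSE_CODONS}
        role = "wanted" if i % 2 == 0 else "unwanted"
        host = _build_host(f"host{i:02d}", role, pref, spec, rng, pool,
                           rrna_root)
        rrna = list(rrna_root)
        for p in schedule[:int(round(150 * t))]:
            rrna[p] = "ACGT"[(("ACGT".index(rrna[p])) + 1) % 4]
        host.rrna_16s = "".join(rrna)
        hosts.append(host)
    return Microbiome(hosts=hosts)
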