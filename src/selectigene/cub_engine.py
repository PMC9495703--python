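"""Codon-usage-bias weights and gene/proteome scores.

Three weighting schemes are supported, all normalised so the best codon
has weight 1:

* **CAI** — relative synonymous codon usage in a highly expressed
  reference gene set: ``w_i = count_i / max_synonymous_count``.
* **tAI** — tRNA availability: ``W_i = sum_j (1 - s_ij) * tGCN_ij`` over
  the anticodons that decode codon *i* (Watson-Crick plus wobble), then
  divided by the maximum.
* **TDR** — typical decoding rate from ribosome-profiling codon
  densities: rate is the reciprocal of the mean normalised footprint
  density, divided by the maximum rate.

A gene's score under any scheme is the geometric mean of its codon
weights, ``exp(mean(log w_i))``; a proteome profile is the mean and
sample standard deviation of those scores across a host's genes.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .codons import (AA_TO_CODONS, CODON_INDEX, CODON_TO_AA, SENSE_CODONS,
                     STOP_CODONS, reverse_complement)

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_model import GeneRecord, HostGenome

SCHEMES = ("CAI", "tAI", "TDR")

ACGT = set("ACGT")


@dataclass
class CodonWeightTable:
    """Per-codon weights w in (0, 1] for one host under one scheme."""

    scheme: str
    host_id: str
    w: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.w]
        if missing:
            raise ValueError(f"weight table missing codons: {missing[:5]}...")
        bad = [c for c, v in self.w.items() if not 0 < v <= 1 + 1e-12]
        if bad:
            raise ValueError(f"weights outside (0,1]: {bad[:5]}")
        self._logw = np.array([math.log(self.w[c]) for c in SENSE_CODONS])

    def logw(self) -> np.ndarray:
        """log-weights indexed by :data:`~selectigene.codons.SENSE_CODONS`."""
        return self._logw

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for c in SENSE_CODONS:
                fh.write(f"{c}\t{self.w[c]:.12g}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: str = "CAI",
                 host_id: str = "") -> "CodonWeightTable":
        w = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                c, v = line.split("\t")[:2]
                w[c.upper()] = float(v)
        return cls(scheme=scheme, host_id=host_id, w=w)


@dataclass
class GeneScore:
    gene_id: str
    scheme: str
    value: float


@dataclass
class ProteomeProfile:
    """Distribution (mu, sigma) of gene CUB scores across one proteome."""

    host_id: str
    scheme: str
    mu: float
    sigma: float
    scores: list[GeneScore] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CAI


def _codon_counts(genes: Iterable) -> dict[str, int]:
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for g in genes:
        cds = g.cds_seq if hasattr(g, "cds_seq") else g
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in counts and set(codon) <= ACGT:
                counts[codon] += 1
    return counts


def cai_weights(reference_genes: list["GeneRecord"], pseudo_weight: float = 0.5,
                host_id: str = "") -> CodonWeightTable:
    """CAI weights from the codon spectrum of a reference gene set.

    Within each synonymous family the most frequent codon gets weight 1
    and the rest ``count / max_count``; codons never observed in the
    reference set get *pseudo_weight* (logs forbid zero weights).
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("empty reference set")
    counts = _codon_counts(reference_genes)
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        fam_max = max(counts[c] for c in codons)
        for c in codons:
            if counts[c] == 0:
                w[c] = pseudo_weight
            else:
                w[c] = counts[c] / fam_max
    return CodonWeightTable(scheme="CAI", host_id=host_id, w=w)


# ---------------------------------------------------------------------------
# tAI


def load_s_values(path: str | Path | None = None) -> dict[str, float]:
    """Wobble interaction penalties s by pairing class (package data by default)."""
    if path is None:
        ref = resources.files("selectigene").joinpath("data/wobble_s.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    s = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        k, v = line.split("\t")[:2]
        s[k] = float(v)
    return s


def build_pairing() -> dict[str, list[tuple[str, str]]]:
    """codon -> [(anticodon, pairing_class)] under the wobble rules.

    Watson-Crick plus third-position wobble (G:U, I:C, I:A, U:G),
    restricted to anticodons whose Watson-Crick codon encodes the same
    amino acid, plus the lysidine special case (anticodon CAT reading
    ATA, class LA).
    """
    wobble_partner = {"T": ("C", "GU"),   # G-starting anticodon reads NNT
                      "C": ("T", "IC"),   # inosine (genomic A) reads NNC
                      "A": ("T", "IA"),   # inosine reads NNA
                      "G": ("A", "UG")}   # U-starting anticodon reads NNG
    pairing: dict[str, list[tuple[str, str]]] = {}
    for codon in SENSE_CODONS:
        pairs = [(reverse_complement(codon), "WC")]
        partner_third, klass = wobble_partner[codon[2]]
        partner = codon[:2] + partner_third
        if partner not in STOP_CODONS and CODON_TO_AA[partner] == CODON_TO_AA[codon]:
            pairs.append((reverse_complement(partner), klass))
        if codon == "ATA":
            pairs.append(("CAT", "LA"))
        pairing[codon] = pairs
    return pairing


@dataclass
class TRNAProfile:
    """A host's tRNA gene copy numbers plus the wobble pairing model."""

    tgcn: dict[str, int]
    s: dict[str, float] = field(default_factory=load_s_values)
    pairing: dict[str, list[tuple[str, str]]] = field(default_factory=build_pairing)

    def __post_init__(self) -> None:
        self.tgcn = {k.upper(): v for k, v in self.tgcn.items()}
        if any(v < 0 for v in self.tgcn.values()):
            raise ValueError("tGCN values must be >= 0")
        if any(not 0 <= v <= 1 for v in self.s.values()):
            raise ValueError("s values must be in [0, 1]")


def tai_weights(profile: TRNAProfile, host_id: str = "") -> CodonWeightTable:
    """tAI weights: ``W_i = sum_j (1 - s_ij) * tGCN_ij`` over recognising
    anticodons, normalised by the maximum; codons with raw weight 0 get
    the geometric mean of the nonzero normalised weights."""
    if not any(v > 0 for v in profile.tgcn.values()):
        raise ValueError("all tGCN values are zero")
    raw = {}
    for codon in SENSE_CODONS:
        raw[codon] = sum((1.0 - profile.s[klass]) * profile.tgcn.get(ac, 0)
                         for ac, klass in profile.pairing[codon])
    wmax = max(raw.values())
    w = {c: v / wmax for c, v in raw.items() if v > 0}
    if len(w) < len(SENSE_CODONS):
        gm = math.exp(sum(math.log(v) for v in w.values()) / len(w))
        for c in SENSE_CODONS:
            w.setdefault(c, gm)
    return CodonWeightTable(scheme="tAI", host_id=host_id, w=w)


# ---------------------------------------------------------------------------
# TDR


def tdr_weights(ribo_density: dict[str, float], host_id: str = "") -> CodonWeightTable:
    """Typical-decoding-rate weights from per-codon footprint densities.

    Decoding rate is the reciprocal of the mean normalised density;
    weights are rates divided by the maximum rate. Codons absent from
    the table get the median observed rate.
    """
    dens = {c: v for c, v in ribo_density.items()
            if c in CODON_INDEX and v is not None}
    if not dens:
        raise ValueError("no codon densities supplied")
    if any(v <= 0 for v in dens.values()):
        raise ValueError("densities must be positive")
    rate = {c: 1.0 / v for c, v in dens.items()}
    med = statistics.median(rate.values())
    full = {c: rate.get(c, med) for c in SENSE_CODONS}
    rmax = max(full.values())
    return CodonWeightTable(scheme="TDR", host_id=host_id,
                            w={c: v / rmax for c, v in full.items()})


# ---------------------------------------------------------------------------
# gene and proteome scores


def codon_index_array(cds: str) -> np.ndarray:
    """Indices into SENSE_CODONS for each scoreable codon of a CDS.

    A terminal stop codon is dropped; codons containing ambiguous
    nucleotides are skipped.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    idx = []
    n = len(cds) // 3
    for i in range(n):
        codon = cds[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            if i == n - 1:
                continue
            raise ValueError(f"internal stop codon at codon {i}")
        if codon in CODON_INDEX:
            idx.append(CODON_INDEX[codon])
    if not idx:
        raise ValueError("no scoreable codons in CDS")
    return np.array(idx, dtype=np.intp)


def gene_score(cds: str, w: CodonWeightTable, gene_id: str = "") -> GeneScore:
    """Geometric-mean codon weight of a CDS: ``exp(mean(log w_i))``."""
    idx = codon_index_array(cds)
    value = float(np.exp(w.logw()[idx].mean()))
    return GeneScore(gene_id=gene_id, scheme=w.scheme, value=value)


def proteome_profile(host: "HostGenome", scheme: str,
                     w: CodonWeightTable) -> ProteomeProfile:
    """Mean and sample SD of gene scores across a host's proteome."""
    if len(host.genes) < 2:
        raise ValueError(f"{host.host_id}: proteome profile needs >= 2 genes")
    scores = [gene_score(g.cds_seq, w, g.gene_id) for g in host.genes]
    vals = [s.value for s in scores]
    mu = statistics.fmean(vals)
    sigma = statistics.stdev(vals)
    if sigma == 0:
        raise ValueError(f"{host.host_id}: degenerate proteome (sigma = 0)")
    return ProteomeProfile(host_id=host.host_id, scheme=scheme,
                           mu=mu, sigma=sigma, scores=scores)


def profile_to_tsv(profile: ProteomeProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in profile.scores:
            fh.write(f"{s.gene_id}\t{s.value:.12g}\n")
    return path


# ---------------------------------------------------------------------------
# per-host convenience


def weights_for(host: "HostGenome", scheme: str,
                reference_fraction: float = 1 / 3) -> CodonWeightTable:
    """Build the weight table for a host under a scheme from its own data."""
    from .sequence_model import select_reference_genes
    if scheme == "CAI":
        ref = select_reference_genes(host, reference_fraction)
        return cai_weights(ref, host_id=host.host_id)
    if scheme == "tAI":
        if not host.tgcn:
            raise ValueError(f"{host.host_id}: tAI requires a tGCN table")
        return tai_weights(TRNAProfile(tgcn=host.tgcn), host_id=host.host_id)
    if scheme == "TDR":
        if not host.tdr:
            raise ValueError(f"{host.host_id}: TDR requires codon densities")
        return tdr_weights(host.tdr, host_id=host.host_id)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
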