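"""Differential codon-usage redesign of an ORF for a wanted/unwanted host split.

Two strategies are implemented:

* **Proteome-relative hill climbing** — greedy ascent over the move set
  "recode every codon of amino acid s to synonymous codon s_i". Each
  candidate is scored by how many proteome standard deviations its CUB
  score sits above each host's proteome mean, combined as
  ``f = alpha * mean_A(dist) - mean_B(dist)``.
* **Individual amino-acid method** — each synonymous family is recoded
  independently to the codon with the best ratio (R) or difference (D)
  selection score across hosts.

The result is always evaluated with the optimization index: the mean
per-sigma CUB improvement in wanted hosts minus that in unwanted hosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import (AA_TO_CODONS, AMINO_ACIDS, CODON_INDEX, SENSE_CODONS,
                     STOP_CODONS, split_codons, translate)
from .cub_engine import (CodonWeightTable, ProteomeProfile, codon_index_array,
                         gene_score, proteome_profile, weights_for)
from .sequence_model import GeneRecord, HostGenome, Microbiome


@dataclass
class HostDistance:
    host_id: str
    dist: float


@dataclass
class NeighborhoodScore:
    candidate_seq: str
    f: float
    alpha: float
    per_host: list[HostDistance] = field(default_factory=list)


@dataclass
class CodonSelectionScore:
    codon: str
    R: float
    D: float


@dataclass
class OptimizationIndex:
    per_host: dict[str, float]
    index: float


@dataclass
class HillClimbResult:
    sequence: str
    trace: list[float]          # accepted f values, strictly increasing
    iterations: int
    converged: bool             # True = local maximum certified


class CubContext:
    """Precomputed per-host weight tables and proteome profiles.

    Building one of these per (microbiome, scheme) amortises the
    reference-set selection and proteome statistics across the many
    candidate evaluations the optimizers make.
    """

    def __init__(self, microbiome: Microbiome, scheme: str,
                 weights: dict[str, CodonWeightTable],
                 profiles: dict[str, ProteomeProfile]):
        microbiome.require_design_ready()
        self.microbiome = microbiome
        self.scheme = scheme
        self.weights = weights
        self.profiles = profiles
        self.host_ids = [h.host_id for h in microbiome.hosts]
        self.wanted = np.array([h.role == "wanted" for h in microbiome.hosts])
        self.logw = np.vstack([weights[h].logw() for h in self.host_ids])
        self.mu = np.array([profiles[h].mu for h in self.host_ids])
        self.sigma = np.array([profiles[h].sigma for h in self.host_ids])
        if np.any(self.sigma <= 0):
            raise ValueError("proteome profile with sigma <= 0")

    @classmethod
    def build(cls, microbiome: Microbiome, scheme: str,
              reference_fraction: float = 1 / 3) -> "CubContext":
        weights = {h.host_id: weights_for(h, scheme, reference_fraction)
                   for h in microbiome.hosts}
        profiles = {h.host_id: proteome_profile(h, scheme, weights[h.host_id])
                    for h in microbiome.hosts}
        return cls(microbiome, scheme, weights, profiles)

    # -- vectorised scoring over codon-index arrays --------------------

    def scores(self, idx: np.ndarray) -> np.ndarray:
        """CUB score of one sequence under every host (geometric mean)."""
        return np.exp(self.logw[:, idx].mean(axis=1))

    def dists(self, idx: np.ndarray) -> np.ndarray:
        return (self.scores(idx) - self.mu) / self.sigma

    def f_of_dists(self, d: np.ndarray, alpha: float) -> float:
        return float(alpha * d[self.wanted].mean() - d[~self.wanted].mean())


def neighborhood_score(candidate: str, profiles: dict[str, ProteomeProfile],
                       weights: dict[str, CodonWeightTable], alpha: float,
                       wanted_ids: set[str] | None = None) -> NeighborhoodScore:
    """Score a candidate ORF: ``alpha * mean_A(dist) - mean_B(dist)``
    with ``dist = (CUB_h(X') - mu_h) / sigma_h`` per host.

    Hosts are split into wanted/unwanted by *wanted_ids*; when omitted,
    every profile whose host_id starts with "wanted" counts as wanted
    (the fixture convention).
    """
    per_host = []
    dists_a, dists_b = [], []
    for hid, prof in profiles.items():
        if prof.sigma <= 0:
            raise ValueError(f"{hid}: sigma must be positive")
        s = gene_score(candidate, weights[hid]).value
        d = (s - prof.mu) / prof.sigma
        per_host.append(HostDistance(host_id=hid, dist=d))
        is_wanted = (hid in wanted_ids) if wanted_ids is not None \
            else hid.startswith("wanted")
        (dists_a if is_wanted else dists_b).append(d)
    if not dists_a or not dists_b:
        raise ValueError("need at least one wanted and one unwanted host")
    f = alpha * float(np.mean(dists_a)) - float(np.mean(dists_b))
    return NeighborhoodScore(candidate_seq=candidate, f=f, alpha=alpha,
                             per_host=per_host)


# ---------------------------------------------------------------------------
# proteome-relative greedy hill climb


def _family_indices() -> dict[str, np.ndarray]:
    return {aa: np.array([CODON_INDEX[c] for c in codons], dtype=np.intp)
            for aa, codons in AA_TO_CODONS.items()}


_FAM_IDX = _family_indices()


def hill_climb(goi: GeneRecord | str, microbiome: Microbiome | None = None,
               scheme: str = "CAI", alpha: float = 1.0, max_iter: int = 200,
               seed: int = 0, context: CubContext | None = None,
               full_output: bool = False):
    """Greedy proteome-relative optimisation of the GOI.

    Moves recode *all* codons of one amino acid to one synonymous codon;
    the best strictly improving move is taken each iteration (ties
    broken toward the lexicographically smaller sequence) until a local
    maximum or *max_iter*. The protein sequence is preserved exactly.

    *seed* is reserved for optional random restarts; the base algorithm
    is deterministic.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    cds = goi.cds_seq if isinstance(goi, GeneRecord) else goi
    ctx = context or CubContext.build(microbiome, scheme)
    codons = split_codons(cds, drop_stop=False)
    stop = ""
    if codons and codons[-1] in STOP_CODONS:
        stop = codons[-1]
        codons = codons[:-1]
    protein = translate(cds)

    counts = np.zeros(len(SENSE_CODONS))
    for c in codons:
        counts[CODON_INDEX[c]] += 1
    L = counts.sum()
    base_sum = ctx.logw @ counts                    # per-host sum of log w

    def f_of_sums(sums: np.ndarray) -> float:
        d = (np.exp(sums / L) - ctx.mu) / ctx.sigma
        return ctx.f_of_dists(d, alpha)

    aas_present = [aa for aa in AMINO_ACIDS if aa in protein]
    trace = [f_of_sums(base_sum)]
    converged = False
    iters = 0
    for _ in range(max_iter):
        iters += 1
        best = None  # (f, candidate codon list, new base_sum, new counts)
        for aa in aas_present:
            fam = _FAM_IDX[aa]
            if len(fam) == 1:
                continue
            fam_total = counts[fam].sum()
            removed = ctx.logw[:, fam] @ counts[fam]
            for j, ci in enumerate(fam):
                new_sum = base_sum - removed + fam_total * ctx.logw[:, ci]
                f = f_of_sums(new_sum)
                if f <= trace[-1]:
                    continue
                if best is None or f > best[0]:
                    cand = list(codons)
                    target = SENSE_CODONS[ci]
                    for k, p in enumerate(protein):
                        if p == aa:
                            cand[k] = target
                    best = (f, cand, new_sum, (fam, ci, fam_total))
                elif f == best[0]:
                    cand = list(codons)
                    target = SENSE_CODONS[ci]
                    for k, p in enumerate(protein):
                        if p == aa:
                            cand[k] = target
                    if cand < best[1]:
                        best = (f, cand, new_sum, (fam, ci, fam_total))
        if best is None:
            converged = True
            break
        f, codons, base_sum, (fam, ci, fam_total) = best
        counts[fam] = 0.0
        counts[ci] = fam_total
        trace.append(f)

    out = "".join(codons) + stop
    assert translate(out) == protein
    result = HillClimbResult(sequence=out, trace=trace, iterations=iters,
                             converged=converged)
    return result if full_output else out


# ---------------------------------------------------------------------------
# individual amino-acid method


def per_codon_scores(weights_by_host: dict[str, CodonWeightTable],
                     roles: dict[str, str], amino_acid: str,
                     d_formula: str = "corrected") -> list[CodonSelectionScore]:
    """Ratio (R) and difference (D) selection scores for one family.

    Each host's weights are renormalised by its within-family maximum.
    R sums wanted-host relative weights minus unwanted-host relative
    weights. D (``corrected``) rewards high wanted-host weight and low
    unwanted-host weight additively; ``printed`` follows the garbled
    published sign convention verbatim.
    """
    if amino_acid not in AA_TO_CODONS:
        raise ValueError(f"unknown amino acid {amino_acid!r}")
    codons = AA_TO_CODONS[amino_acid]
    out = []
    for codon in codons:
        R = D = 0.0
        for hid, table in weights_by_host.items():
            fmax = max(table.w[c] for c in codons)
            rel = table.w[codon] / fmax
            if roles[hid] == "wanted":
                R += rel
                D += rel if d_formula == "corrected" \
                    else (1.0 - table.w[codon] + fmax)
            else:
                R -= rel
                D += (1.0 - rel) if d_formula == "corrected" \
                    else (table.w[codon] - fmax)
        out.append(CodonSelectionScore(codon=codon, R=R, D=D))
    return out


def family_winner(scores: list[CodonSelectionScore], kind: str) -> str:
    """argmax of R or D; ties go to the lexicographically smallest codon."""
    key = (lambda s: s.R) if kind == "R" else (lambda s: s.D)
    best = max(key(s) for s in scores)
    return min(s.codon for s in scores if key(s) == best)


def individual_optimize(goi: GeneRecord | str, microbiome: Microbiome | None = None,
                        scheme: str = "CAI", score_kind: str = "R",
                        d_formula: str = "corrected",
                        context: CubContext | None = None) -> str:
    """Recode every position to its family's winning codon."""
    if score_kind not in ("R", "D"):
        raise ValueError("score_kind must be 'R' or 'D'")
    cds = goi.cds_seq if isinstance(goi, GeneRecord) else goi
    ctx = context or CubContext.build(microbiome, scheme)
    roles = {h.host_id: h.role for h in ctx.microbiome.hosts}
    protein = translate(cds)
    winners = {}
    for aa in sorted(set(protein)):
        scores = per_codon_scores(ctx.weights, roles, aa, d_formula)
        winners[aa] = family_winner(scores, score_kind)
    codons = split_codons(cds, drop_stop=False)
    stop = codons[-1] if codons[-1] in STOP_CODONS else ""
    out = "".join(winners[p] for p in protein) + stop
    assert translate(out) == protein
    return out


# ---------------------------------------------------------------------------
# result evaluation


def optimization_index(original: str, engineered: str,
                       microbiome: Microbiome | None = None,
                       scheme: str = "CAI",
                       context: CubContext | None = None) -> OptimizationIndex:
    """Per-sigma CUB change per host and the final optimization index
    ``mean_A(Score) - mean_B(Score)`` with
    ``Score_h = (CUB_h(X') - CUB_h(X)) / sigma_h``."""
    if translate(original) != translate(engineered):
        raise ValueError("original and engineered sequences encode different proteins")
    ctx = context or CubContext.build(microbiome, scheme)
    idx_orig = codon_index_array(original)
    idx_eng = codon_index_array(engineered)
    score_h = (ctx.scores(idx_eng) - ctx.scores(idx_orig)) / ctx.sigma
    per_host = dict(zip(ctx.host_ids, (float(v) for v in score_h)))
    index = float(score_h[ctx.wanted].mean() - score_h[~ctx.wanted].mean())
    return OptimizationIndex(per_host=per_host, index=index)
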