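"""Contrastive promoter-motif construction, promoter ranking, and tailoring.

The pipeline mirrors classic MEME-suite workflows: per-host motif
discovery (enriched in strong promoters vs intergenic sequence for
wanted hosts; the reverse contrast — "anti-motifs" — for unwanted
hosts), Spearman-correlation motif similarity with per-host thresholds
calibrated against random PSSMs, an aggregated cross-host motif score,
and a percentile cut that yields one final motif set F. Candidate
promoters are then ranked by a MAST-style combined E-value of their best
per-motif hits, and top promoters are tailored by correcting individual
motif mismatches.

Discovery and scanning run through an internal backend by default
(enriched-k-mer seeding with Fisher exact tests + EM refinement;
quantised log-odds scanning with exact DP position p-values). The MEME
suite binaries (STREME/MAST) can be used instead when installed.
"""

from __future__ import annotations

import logging
import math
import shutil
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MIN_W, MAX_W = 6, 20

#: granularity of quantised log-odds scores (integer units of 0.01 bits)
SCORE_SCALE = 100


class BackendUnavailableError(RuntimeError):
    """An external MEME-suite binary was requested but is not installed."""


@dataclass
class PSSM:
    """A 4 x L nucleotide probability matrix (rows A, C, G, T)."""

    probs: np.ndarray
    source_host: str = ""
    evalue: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PSSM must have 4 rows (A, C, G, T)")
        if not MIN_W <= self.probs.shape[1] <= MAX_W:
            raise ValueError(f"PSSM length must be in [{MIN_W}, {MAX_W}]")
        if np.any(self.probs < 0):
            raise ValueError("PSSM probabilities must be non-negative")
        col = self.probs.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-9):
            raise ValueError("PSSM columns must sum to 1")
        if self.evalue <= 0:
            raise ValueError("significance must be positive")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PSSM":
        return PSSM(probs=self.probs[::-1, ::-1].copy(),
                    source_host=self.source_host, evalue=self.evalue,
                    name=self.name + "_rc" if self.name else "")


@dataclass
class SimilarityThreshold:
    host_id: str
    D_h: float
    X: float = 95.0
    n_random: int = 100
    seed: int = 0


@dataclass
class MotifScore:
    motif: PSSM
    delta: dict[str, int]
    aggregated: float
    alpha: float


@dataclass
class MappedMotif:
    motif: PSSM
    offset: int
    strand: str
    mismatches: list[int]   # positions within the motif window


@dataclass
class PromoterRank:
    promoter_id: str
    sequence: str
    evalue: float
    mapped_motifs: list[MappedMotif] = field(default_factory=list)


# ---------------------------------------------------------------------------
# encoding helpers


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int codes; non-ACGT becomes -1."""
    return np.array([BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _windows(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """All clean (ACGT-only) windows of width w and their offsets."""
    if len(codes) < w:
        return np.empty((0, w), dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    ok = (win >= 0).all(axis=1)
    return win[ok], np.nonzero(ok)[0]


def background_from(sequences: list[str]) -> np.ndarray:
    """0-order background base frequencies (with a +1 pseudocount)."""
    counts = np.ones(4)
    for s in sequences:
        codes = _encode(s)
        for b in range(4):
            counts[b] += int((codes == b).sum())
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# internal motif discovery: enriched k-mer seeds + EM refinement


def _presence_counts(seqs: list[str], w: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        seen = {s[i:i + w] for i in range(len(s) - w + 1)}
        for kmer in seen:
            if set(kmer) <= set(BASES):
                out[kmer] = out.get(kmer, 0) + 1
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _kmer_duplicate(a: str, b: str) -> bool:
    """True if two seed k-mers are near-identical up to a small shift
    (discovery should not report shifted variants of one motif)."""
    if a in b or b in a:
        return True
    if len(a) == len(b) and _hamming(a, b) <= 2:
        return True
    for shift in (-2, -1, 1, 2):
        lo_a = max(0, shift)
        lo_b = max(0, -shift)
        n = min(len(a) - lo_a, len(b) - lo_b)
        if n >= min(len(a), len(b)) - 2 and \
                _hamming(a[lo_a:lo_a + n], b[lo_b:lo_b + n]) <= 1:
            return True
    return False


def _em_refine(seed_kmer: str, primary: list[str], bg: np.ndarray,
               n_iter: int = 4, pseudo: float = 0.25) -> np.ndarray:
    """ZOOPS EM refinement of a k-mer seed into a PSSM."""
    w = len(seed_kmer)
    probs = np.full((4, w), 0.1 / 3)
    for j, b in enumerate(seed_kmer):
        probs[BASE_INDEX[b], j] = 0.9
    wins_all, counts_per_seq = [], []
    for s in primary:
        win, _ = _windows(_encode(s), w)
        wins_all.append(win)
        counts_per_seq.append(len(win))
    gamma = 0.5  # prior probability a sequence carries one site (ZOOPS)
    for _ in range(n_iter):
        weighted = np.full((4, w), pseudo)
        logm = np.log(probs + 1e-12)
        logb = np.log(bg)
        for win in wins_all:
            if len(win) == 0:
                continue
            lr = np.zeros(len(win))        # log likelihood-ratio per window
            for j in range(w):
                lr += logm[win[:, j], j] - logb[win[:, j]]
            m = lr.max()
            r = np.exp(lr - m)
            # P(window i is the site | data), vs P(no site) = 1 - gamma
            z = (gamma / len(win)) * r
            zn = z / (z.sum() + (1 - gamma) * math.exp(-m))
            for j in range(w):
                np.add.at(weighted[:, j], win[:, j], zn)
        probs = weighted / weighted.sum(axis=0, keepdims=True)
    return probs


def discover_motifs(primary: list[str], control: list[str],
                    backend: str = "internal", seed: int = 0,
                    significance: float = 0.05,
                    widths: tuple[int, ...] = (6, 8),
                    max_motifs: int = 5, source_host: str = "") -> list[PSSM]:
    """Motifs enriched in *primary* relative to *control* sequences.

    The internal backend counts k-mer presence per sequence, tests
    enrichment with a one-sided Fisher exact test (Bonferroni-corrected
    over the k-mers tested), collapses near-duplicate seeds, and refines
    each surviving seed into a PSSM by EM against a 0-order control
    background. Returned motifs carry the corrected enrichment p-value
    as their significance and satisfy ``significance <= 0.05`` by
    construction of the cut.
    """
    if not primary or not control:
        raise ValueError("primary and control sets must both be non-empty")
    if min(len(s) for s in primary) < MIN_W:
        raise ValueError(f"primary sequences shorter than minimum width {MIN_W}")
    if backend == "external":
        return _discover_streme(primary, control, significance)
    if backend != "internal":
        raise ValueError(f"unknown backend {backend!r}")

    n1, n2 = len(primary), len(control)
    bg = background_from(control)
    candidates: list[tuple[float, str]] = []
    for w in widths:
        if w > min(len(s) for s in primary):
            continue
        pres1 = _presence_counts(primary, w)
        pres2 = _presence_counts(control, w)
        n_tested = len(pres1)
        for kmer, a in pres1.items():
            if a < max(3, 0.2 * n1):
                continue
            b = pres2.get(kmer, 0)
            if a / n1 <= b / n2:
                continue
            p = stats.fisher_exact([[a, n1 - a], [b, n2 - b]],
                                   alternative="greater")[1]
            p_corr = min(1.0, p * n_tested)
            if p_corr <= significance:
                candidates.append((p_corr, kmer))
    candidates.sort(key=lambda t: (t[0], t[1]))

    selected: list[tuple[float, str]] = []
    for p, kmer in candidates:
        if not any(_kmer_duplicate(chosen, kmer) for _, chosen in selected):
            selected.append((p, kmer))
        if len(selected) >= max_motifs:
            break

    motifs = []
    for i, (p, kmer) in enumerate(selected):
        probs = _em_refine(kmer, primary, bg)
        motifs.append(PSSM(probs=probs, source_host=source_host,
                           evalue=max(p, 1e-300),
                           name=f"{source_host or 'motif'}_{i + 1}"))
    return motifs


def _discover_streme(primary: list[str], control: list[str],
                     significance: float) -> list[PSSM]:  # pragma: no cover
    if shutil.which("streme") is None:
        raise BackendUnavailableError(
            "STREME binary not found on PATH; rerun with backend='internal'")
    import subprocess
    import tempfile
    from pathlib import Path
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        for name, seqs in (("primary.fa", primary), ("control.fa", control)):
            with open(td / name, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f">s{i}\n{s}\n")
        subprocess.run(
            ["streme", "--p", str(td / "primary.fa"), "--n",
             str(td / "control.fa"), "--minw", str(MIN_W), "--maxw",
             str(MAX_W), "--order", "3", "--thresh", str(significance),
             "--oc", str(td / "out")],
            check=True, capture_output=True)
        return read_meme(td / "out" / "streme.txt")


# ---------------------------------------------------------------------------
# per-host motif sets


def enhancing_and_anti_motifs(host, fraction: float = 1 / 3,
                              backend: str = "internal", seed: int = 0,
                              chunk: int = 200) -> tuple[list[PSSM], list[PSSM]]:
    """(S_enh, S_anti) for one host.

    Wanted hosts get transcription-enhancing motifs (strong promoters as
    primary, intergenic as control); unwanted hosts get anti-motifs
    (intergenic as primary, strong promoters as control). Intergenic
    stretches are chopped into *chunk*-bp pieces so both sets have
    comparable sequence lengths.
    """
    from .sequence_model import select_reference_genes
    if host.regions is None or not host.regions.promoters:
        raise ValueError(f"{host.host_id}: no promoters; run extract_regions first")
    top_ids = {g.gene_id for g in select_reference_genes(host, fraction)}
    strong = [seq for gid, seq in host.regions.promoters if gid in top_ids]
    if not strong:
        raise ValueError(f"{host.host_id}: no promoters for the strong gene set")
    inter = []
    for s in host.regions.intergenic:
        for i in range(0, len(s), chunk):
            piece = s[i:i + chunk]
            if len(piece) >= MIN_W:
                inter.append(piece)
    if not inter:
        raise ValueError(f"{host.host_id}: no intergenic sequence")
    if host.role == "wanted":
        enh = discover_motifs(strong, inter, backend=backend, seed=seed,
                              source_host=host.host_id)
        return enh, []
    anti = discover_motifs(inter, strong, backend=backend, seed=seed,
                           source_host=host.host_id)
    return [], anti


# ---------------------------------------------------------------------------
# motif similarity and thresholds


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def pssm_similarity(m1: PSSM, m2: PSSM) -> float:
    """Spearman correlation between two PSSMs, maximised over ungapped
    offsets of the shorter within the longer and over reverse
    complement; symmetric in its arguments."""
    short, long_ = (m1, m2) if m1.length <= m2.length else (m2, m1)
    best = -1.0
    for cand in (long_, long_.reverse_complement()):
        for off in range(cand.length - short.length + 1):
            sl = cand.probs[:, off:off + short.length]
            c = _spearman(short.probs.ravel(order="F"), sl.ravel(order="F"))
            best = max(best, c)
    return best


def random_pssm(rng: np.random.Generator) -> PSSM:
    """A random PSSM: length uniform on [6, 20], columns ~ Dirichlet(1)."""
    L = int(rng.integers(MIN_W, MAX_W + 1))
    probs = rng.dirichlet(np.ones(4), size=L).T
    return PSSM(probs=probs, name="random")


def calibrate_threshold(S_h: list[PSSM], X: float = 95.0, n_random: int = 100,
                        seed: int = 0, host_id: str = "") -> SimilarityThreshold:
    """Similarity threshold D_h: the X-percentile (linear interpolation)
    of correlations between the host's motifs and random PSSMs."""
    if not S_h:
        raise ValueError("motif set S_h must be non-empty")
    rng = np.random.default_rng(seed)
    randoms = [random_pssm(rng) for _ in range(n_random)]
    corrs = [pssm_similarity(m, r) for m in S_h for r in randoms]
    d = float(np.percentile(corrs, X))
    return SimilarityThreshold(host_id=host_id or (S_h[0].source_host or ""),
                               D_h=d, X=X, n_random=n_random, seed=seed)


# ---------------------------------------------------------------------------
# final motif set (aggregated scoring + percentile cut)


def build_final_set(S_by_host: dict[str, list[PSSM]], microbiome,
                    alpha: float = 0.5, Y: float = 75.0, X: float = 95.0,
                    n_random: int = 100, seed: int = 0,
                    full_output: bool = False):
    """Construct the final motif set F from per-host motif sets.

    C is the union of wanted hosts' enhancing motifs. For each motif m
    and host h, ``delta_h(m) = 1`` if some motif of S_h correlates with
    m at or above the host's threshold D_h. The aggregated score is
    ``alpha * sum_A delta + (1 - alpha) * sum_B delta`` (unwanted hosts'
    sets are anti-motifs, so matching them is desirable). F keeps the
    motifs scoring strictly above the Y-percentile of all scores.
    """
    wanted_ids = [h.host_id for h in microbiome.A]
    unwanted_ids = [h.host_id for h in microbiome.B]
    C, seen = [], set()
    for hid in wanted_ids:
        for m in S_by_host.get(hid, []):
            if id(m) not in seen:     # C is a union: shared objects once
                seen.add(id(m))
                C.append(m)
    if not C:
        raise ValueError("initial motif set C is empty (no wanted-host motifs)")
    thresholds = {}
    for hid in wanted_ids + unwanted_ids:
        if S_by_host.get(hid):
            thresholds[hid] = calibrate_threshold(
                S_by_host[hid], X=X, n_random=n_random, seed=seed, host_id=hid)

    def delta(m: PSSM, hid: str) -> int:
        S = S_by_host.get(hid, [])
        if not S:
            return 0
        D = thresholds[hid].D_h
        return int(any(pssm_similarity(m, mp) >= D for mp in S))

    scored = []
    for m in C:
        d = {hid: delta(m, hid) for hid in wanted_ids + unwanted_ids}
        agg = (alpha * sum(d[h] for h in wanted_ids)
               + (1 - alpha) * sum(d[h] for h in unwanted_ids))
        scored.append(MotifScore(motif=m, delta=d, aggregated=agg, alpha=alpha))
    cut = float(np.percentile([s.aggregated for s in scored], Y))
    F = [s.motif for s in scored if s.aggregated > cut]
    if not F:
        log.warning("final motif set F is empty (all aggregated scores <= "
                    "P%g = %g)", Y, cut)
    return (F, scored) if full_output else F


# ---------------------------------------------------------------------------
# promoter ranking (MAST-style combined E-values)


def _quantized_logodds(motif: PSSM, bg: np.ndarray) -> np.ndarray:
    p = motif.probs + 1e-4
    p = p / p.sum(axis=0, keepdims=True)
    return np.rint(SCORE_SCALE * np.log2(p / bg[:, None])).astype(np.int64)


def _score_pvalue_table(scores: np.ndarray, bg: np.ndarray,
                        ) -> tuple[np.ndarray, int]:
    """Exact null distribution of the quantised window score by DP.

    Returns (tail, smin): ``tail[s - smin]`` = P(score >= s) under the
    0-order background.
    """
    w = scores.shape[1]
    smin = int(scores.min(axis=0).sum())
    lo0, hi0 = int(scores[:, 0].min()), int(scores[:, 0].max())
    dist = np.zeros(hi0 - lo0 + 1)
    for b in range(4):
        dist[int(scores[b, 0]) - lo0] += bg[b]
    for j in range(1, w):
        cmin, cmax = int(scores[:, j].min()), int(scores[:, j].max())
        new = np.zeros(len(dist) + cmax - cmin)
        for b in range(4):
            sh = int(scores[b, j]) - cmin
            new[sh:sh + len(dist)] += bg[b] * dist
        dist = new
    tail = dist[::-1].cumsum()[::-1]
    return tail, smin


def _best_hit(motif: PSSM, codes: np.ndarray, lods: np.ndarray,
              ) -> tuple[int, int] | None:
    """(best integer score, offset) of the motif on a sequence, or None."""
    win, offs = _windows(codes, motif.length)
    if len(win) == 0:
        return None
    ws = np.zeros(len(win), dtype=np.int64)
    for j in range(motif.length):
        ws += lods[win[:, j], j]
    k = int(ws.argmax())
    return int(ws[k]), int(offs[k])


def _combined_pvalue(pvals: list[float]) -> float:
    """MAST convention: P that a product of k independent uniform
    p-values is <= the observed product Q: ``Q * sum_{i<k} (-ln Q)^i / i!``."""
    q = 1.0
    for p in pvals:
        q *= max(min(p, 1.0), 1e-300)
    if q >= 1.0:
        return 1.0
    lnq = -math.log(q)
    term, total = 1.0, 1.0
    for i in range(1, len(pvals)):
        term *= lnq / i
        total += term
    return min(1.0, q * total)


def rank_promoters(F: list[PSSM], candidate_promoters: list[tuple[str, str]],
                   backend: str = "internal",
                   background: np.ndarray | None = None) -> list[PromoterRank]:
    """Rank candidate promoters by combined motif-match E-value.

    For each promoter the best hit of each motif in F yields a position
    p-value (exact, from the quantised log-odds null distribution),
    converted to a sequence-level p-value over the scanned positions;
    the per-motif p-values are combined with the MAST product
    convention, and multiplied by the number of candidates to give an
    E-value. Promoters are returned sorted ascending (ties broken by
    promoter_id).
    """
    if not F:
        raise ValueError("final motif set F is empty")
    if backend == "external" and shutil.which("mast") is None:
        raise BackendUnavailableError(
            "MAST binary not found on PATH; rerun with backend='internal'")
    bg = background if background is not None else np.full(4, 0.25)
    tables = []
    for m in F:
        lods = _quantized_logodds(m, bg)
        tail, smin = _score_pvalue_table(lods, bg)
        tables.append((m, lods, tail, smin))
    n_cand = len(candidate_promoters)
    ranks = []
    for pid, seq in candidate_promoters:
        codes = _encode(seq)
        pvals, mapped = [], []
        for m, lods, tail, smin in tables:
            hit = _best_hit(m, codes, lods)
            if hit is None:
                pvals.append(1.0)
                continue
            s, off = hit
            p_pos = float(tail[s - smin])
            n_off = max(1, len(codes) - m.length + 1)
            p_seq = 1.0 - (1.0 - min(p_pos, 1.0)) ** n_off
            pvals.append(max(p_seq, 1e-300))
            cons = m.consensus
            window = seq[off:off + m.length].upper()
            mism = [j for j in range(m.length) if window[j] != cons[j]]
            mapped.append(MappedMotif(motif=m, offset=off, strand="+",
                                      mismatches=mism))
        evalue = _combined_pvalue(pvals) * n_cand
        ranks.append(PromoterRank(promoter_id=pid, sequence=seq.upper(),
                                  evalue=evalue, mapped_motifs=mapped))
    ranks.sort(key=lambda r: (r.evalue, r.promoter_id))
    return ranks


def tailor_promoter(p: PromoterRank) -> list[str]:
    """Variants of a promoter with motif mismatches corrected.

    Emits the original, one variant per single mismatch position (set to
    the motif's modal nucleotide), and one variant with every mismatch
    corrected. With no mismatches only the original is returned.
    """
    fixes: list[tuple[int, str]] = []   # (absolute position, replacement base)
    for mm in p.mapped_motifs:
        cons = mm.motif.consensus
        for j in mm.mismatches:
            fixes.append((mm.offset + j, cons[j]))
    out = [p.sequence]
    if not fixes:
        return out
    for pos, base in fixes:
        v = p.sequence[:pos] + base + p.sequence[pos + 1:]
        out.append(v)
    full = list(p.sequence)
    for pos, base in fixes:
        full[pos] = base
    full_s = "".join(full)
    if full_s not in out:
        out.append(full_s)
    return out


# ---------------------------------------------------------------------------
# MEME motif text format


def write_meme(motifs: list[PSSM], path, background: np.ndarray | None = None):
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for i, m in enumerate(motifs):
            name = m.name or f"motif_{i + 1}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length} "
                     f"nsites= 20 E= {m.evalue:.3g}\n")
            for j in range(m.length):
                fh.write(" ".join(f"{m.probs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")
    return path


def read_meme(path) -> list[PSSM]:
    motifs = []
    name, rows, evalue = None, [], 1.0

    def flush():
        if name and rows:
            motifs.append(PSSM(probs=np.array(rows).T, name=name, evalue=evalue))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
                rows, evalue = [], 1.0
            elif line.startswith("letter-probability"):
                if "E=" in line:
                    evalue = float(line.split("E=")[1].split()[0])
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(x) for x in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
    flush()
    return motifs
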