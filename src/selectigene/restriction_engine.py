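"""Restriction-site engineering on an ORF under the synonymous-protein constraint.

Recognition sites (IUPAC strings, from a REBASE-like repertoire file)
are classified by which side of the wanted/unwanted split recognises
them. The editor then (1) greedily realises *potential* unwanted-only
sites — placements reachable by synonymous codon changes — prioritising
placements that raise the number of unwanted hosts with at least one
site, and (2) removes every site recognised by any wanted host where a
synonymous escape exists, preferring minimal codon changes that least
perturb the wanted-host codon adaptation. Both strands are scanned
(restriction enzymes act on double-stranded DNA); the protein sequence
is asserted unchanged around every edit.

Insertion runs before removal: inserting an unwanted-host site can
create a new wanted-recognised site, which the removal pass must see.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .codons import (AA_TO_CODONS, CODON_INDEX, CODON_TO_AA, IUPAC_SETS,
                     STOP_CODONS, is_iupac, reverse_complement, translate)

log = logging.getLogger(__name__)

MIN_SITE_LENGTH = 4


@dataclass
class EnzymeRepertoire:
    host_id: str
    sites: set[str]

    def __post_init__(self) -> None:
        bad = [s for s in self.sites if not is_iupac(s) or len(s) < MIN_SITE_LENGTH]
        if bad:
            raise ValueError(f"invalid recognition sites: {bad[:5]}")


@dataclass
class SiteOccurrence:
    site: str
    offset: int                       # 0-based on the coding strand
    strand: str                       # '+' or '-'
    status: str                       # 'present' | 'potential'
    recognizers_wanted: set[str] = field(default_factory=set)
    recognizers_unwanted: set[str] = field(default_factory=set)
    required_codon_changes: list[tuple[int, str]] = field(default_factory=list)
    conflict_set: set[tuple[str, int, str]] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.site, self.offset, self.strand)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.offset, self.offset + len(self.site))

    @property
    def codon_span(self) -> tuple[int, int]:
        return (self.offset // 3, (self.offset + len(self.site) - 1) // 3)


@dataclass
class SiteClassification:
    wanted_only: set[str]
    unwanted_only: set[str]
    shared: set[str]
    recognizers: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# REBASE parsing


def _species_key(organism: str) -> str:
    return " ".join(organism.split()[:2])


def _clean_site(raw: str) -> str | None:
    site = re.sub(r"\(.*?\)", "", raw).replace("^", "").strip().upper()
    if not site or site == "?":
        return None
    if not is_iupac(site) or len(site) < MIN_SITE_LENGTH:
        return None
    return site


def parse_rebase(path: str | Path) -> dict[str, EnzymeRepertoire]:
    """Read per-organism recognition-site repertoires.

    Two dialects are accepted: the REBASE flat enzyme format (records of
    ``<1>``-style numbered fields; ``<3>`` organism, ``<5>`` recognition
    sequence) and a TSV (``organism<TAB>site;site;...``). Strains of the
    same species are merged; 'Unidentified bacterium' entries are
    dropped; malformed sites are skipped with a warning.
    """
    path = Path(path)
    text = path.read_text()
    per_species: dict[str, set[str]] = {}

    def add(organism: str, raw_site: str) -> None:
        organism = organism.strip()
        if not organism or organism.lower().startswith("unidentified bacterium"):
            return
        site = _clean_site(raw_site)
        if site is None:
            if raw_site.strip():
                log.warning("skipping malformed site %r (%s)", raw_site, organism)
            return
        per_species.setdefault(_species_key(organism), set()).add(site)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if any(ln.lstrip().startswith("<1>") for ln in lines):
        org, site = None, None
        for ln in lines:
            ln = ln.strip()
            if ln.startswith("<1>"):
                if org and site:
                    add(org, site)
                org, site = None, None
            elif ln.startswith("<3>"):
                org = ln[3:]
            elif ln.startswith("<5>"):
                site = ln[3:]
        if org and site:
            add(org, site)
    else:
        for ln in lines:
            if ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            for raw in parts[1].split(";"):
                if raw.strip():
                    add(parts[0], raw)
    return {sp: EnzymeRepertoire(host_id=sp, sites=sites)
            for sp, sites in per_species.items()}


# ---------------------------------------------------------------------------
# classification


def classify_sites(microbiome) -> SiteClassification:
    """Partition every recognition site by which host roles recognise it."""
    rec: dict[str, tuple[set[str], set[str]]] = {}
    for h in microbiome.hosts:
        for s in h.enzymes:
            s = s.upper()
            rec.setdefault(s, (set(), set()))
            rec[s][0 if h.role == "wanted" else 1].add(h.host_id)
    wanted_only, unwanted_only, shared = set(), set(), set()
    for s, (wa, un) in rec.items():
        if wa and un:
            shared.add(s)
        elif wa:
            wanted_only.add(s)
        else:
            unwanted_only.add(s)
    return SiteClassification(wanted_only=wanted_only, unwanted_only=unwanted_only,
                              shared=shared, recognizers=rec)


# ---------------------------------------------------------------------------
# site matching (present + potential)


@lru_cache(maxsize=8192)
def _site_regex(site: str) -> re.Pattern:
    body = "".join("[" + "".join(sorted(IUPAC_SETS[ch])) + "]" for ch in site)
    return re.compile(f"(?=({body}))")


def present_offsets(seq: str, site: str, strand: str) -> list[int]:
    pattern = site if strand == "+" else reverse_complement(site)
    return [m.start() for m in _site_regex(pattern).finditer(seq)]


def _realize_at(seq: str, pattern: str, offset: int,
                ) -> list[tuple[int, str]] | None:
    """Synonymous codon changes that make *pattern* match at *offset*.

    Returns the change list (possibly empty, meaning already present) or
    None when no synonymous assignment can realise the site. The
    terminal stop codon is never altered.
    """
    L = len(pattern)
    n_codons = len(seq) // 3
    changes: list[tuple[int, str]] = []
    k0, k1 = offset // 3, (offset + L - 1) // 3
    for k in range(k0, k1 + 1):
        lo = max(offset, 3 * k)
        hi = min(offset + L, 3 * k + 3)
        cur = seq[3 * k:3 * k + 3]
        wanted_chars = [(p - 3 * k, pattern[p - offset]) for p in range(lo, hi)]
        if all(cur[i] in IUPAC_SETS[ch] for i, ch in wanted_chars):
            continue
        if cur in STOP_CODONS or cur not in CODON_TO_AA:
            return None
        options = [c for c in AA_TO_CODONS[CODON_TO_AA[cur]]
                   if all(c[i] in IUPAC_SETS[ch] for i, ch in wanted_chars)]
        if not options:
            return None
        changes.append((k, options[0]))
    return changes


def _realize_options(seq: str, pattern: str, offset: int) -> list[list[str]] | None:
    """Per overlapped codon, the synonymous codons compatible with the site."""
    L = len(pattern)
    k0, k1 = offset // 3, (offset + L - 1) // 3
    out = []
    for k in range(k0, k1 + 1):
        lo = max(offset, 3 * k)
        hi = min(offset + L, 3 * k + 3)
        cur = seq[3 * k:3 * k + 3]
        wanted_chars = [(p - 3 * k, pattern[p - offset]) for p in range(lo, hi)]
        if cur in STOP_CODONS or cur not in CODON_TO_AA:
            if all(cur[i] in IUPAC_SETS[ch] for i, ch in wanted_chars):
                out.append([cur])
                continue
            return None
        options = [c for c in AA_TO_CODONS[CODON_TO_AA[cur]]
                   if all(c[i] in IUPAC_SETS[ch] for i, ch in wanted_chars)]
        if not options:
            return None
        out.append(options)
    return out


_BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}


def _pattern_masks(pattern: str) -> tuple[int, ...]:
    return tuple(sum(_BASE_MASK[b] for b in IUPAC_SETS[ch]) for ch in pattern)


@lru_cache(maxsize=4096)
def _possible_masks(seq: str) -> tuple[int, ...]:
    """Per position, the bitmask of bases reachable by synonymous swaps."""
    masks = []
    for k in range(len(seq) // 3):
        cur = seq[3 * k:3 * k + 3]
        if cur in CODON_TO_AA:
            options = AA_TO_CODONS[CODON_TO_AA[cur]]
        else:
            options = (cur,)
        for i in range(3):
            masks.append(sum(set(_BASE_MASK.get(c[i], 0) for c in options)))
    return tuple(masks)


@lru_cache(maxsize=65536)
def _present_matches(seq: str, site: str) -> tuple[tuple[int, str], ...]:
    """Current placements of one site on both strands (palindromes once)."""
    strands = ("+",) if reverse_complement(site) == site else ("+", "-")
    out = []
    for strand in strands:
        pattern = site if strand == "+" else reverse_complement(site)
        for off in present_offsets(seq, pattern, "+"):
            out.append((off, strand))
    return tuple(out)


@lru_cache(maxsize=8192)
def _site_matches(seq: str, site: str) -> tuple[tuple, tuple]:
    """(present, potential) placements of one site on one ORF (both strands).

    present: ((offset, strand), ...); potential: ((offset, strand,
    changes), ...) with changes a tuple of (codon index, new codon).
    Palindromic sites are scanned on the forward strand only.
    """
    strands = ("+",) if reverse_complement(site) == site else ("+", "-")
    possible = np.asarray(_possible_masks(seq), dtype=np.uint8)
    present = list(_present_matches(seq, site))
    potential = []
    L = len(site)
    if len(seq) >= L:
        windows = np.lib.stride_tricks.sliding_window_view(possible, L)
        for strand in strands:
            pattern = site if strand == "+" else reverse_complement(site)
            hits = {off for off, s in present if s == strand}
            pmask = np.asarray(_pattern_masks(pattern), dtype=np.uint8)
            feasible = np.nonzero((windows & pmask).all(axis=1))[0]
            for off in feasible:
                off = int(off)
                if off in hits:
                    continue
                changes = _realize_at(seq, pattern, off)
                if changes:
                    potential.append((off, strand, tuple(changes)))
    return tuple(present), tuple(potential)


def find_occurrences(orf: str, sites: set[str],
                     classification: SiteClassification | None = None,
                     ) -> list[SiteOccurrence]:
    """Locate every current and potential placement of the given sites.

    Potential placements are those realisable purely by synonymous codon
    substitutions of the overlapping codons; their conflict sets link
    potential placements whose codon spans overlap.
    """
    orf = orf.upper()
    occs: list[SiteOccurrence] = []
    for site in sorted(sites):
        present, potential = _site_matches(orf, site.upper())
        wa, un = (classification.recognizers.get(site.upper(), (set(), set()))
                  if classification else (set(), set()))
        for off, strand in present:
            occs.append(SiteOccurrence(site=site, offset=off, strand=strand,
                                       status="present",
                                       recognizers_wanted=set(wa),
                                       recognizers_unwanted=set(un)))
        for off, strand, changes in potential:
            occs.append(SiteOccurrence(site=site, offset=off, strand=strand,
                                       status="potential",
                                       recognizers_wanted=set(wa),
                                       recognizers_unwanted=set(un),
                                       required_codon_changes=list(changes)))
    pot = sorted((o for o in occs if o.status == "potential"),
                 key=lambda o: o.codon_span)
    active: list[SiteOccurrence] = []
    for o in pot:                      # sweep over sorted codon spans
        active = [a for a in active if a.codon_span[1] >= o.codon_span[0]]
        for a in active:
            a.conflict_set.add(o.key)
            o.conflict_set.add(a.key)
        active.append(o)
    return occs


# ---------------------------------------------------------------------------
# scanning summaries


def _present_sites(seq: str, sites: set[str]) -> list[tuple[str, int, str]]:
    out = []
    for site in sites:
        for off, strand in _present_matches(seq, site.upper()):
            out.append((site, off, strand))
    return out


def hosts_with_site(seq: str, microbiome) -> tuple[set[str], set[str]]:
    """(wanted host ids, unwanted host ids) with >= 1 recognised site."""
    wanted, unwanted = set(), set()
    for h in microbiome.hosts:
        for site in h.enzymes:
            if _present_matches(seq.upper(), site.upper()):
                (wanted if h.role == "wanted" else unwanted).add(h.host_id)
                break
    return wanted, unwanted


# ---------------------------------------------------------------------------
# insertion


def _apply_changes(seq: str, changes: list[tuple[int, str]]) -> str:
    out = list(seq)
    for k, codon in changes:
        out[3 * k:3 * k + 3] = codon
    return "".join(out)


def _removable_keeping(seq: str, occ_key: tuple[str, int, str],
                       keep_intervals: list[tuple[int, int]],
                       avoid_sites: set[str]) -> bool:
    """Can the present site at *occ_key* be broken synonymously without
    touching any codon inside *keep_intervals*?"""
    site, off, strand = occ_key
    pattern = site if strand == "+" else reverse_complement(site)
    # look for a synonymous change outside keep_intervals that breaks the match
    k0 = off // 3
    k1 = (off + len(site) - 1) // 3
    keep_codons = set()
    for lo, hi in keep_intervals:
        keep_codons.update(range(lo // 3, (hi - 1) // 3 + 1))
    for k in range(k0, k1 + 1):
        if k in keep_codons:
            continue
        cur = seq[3 * k:3 * k + 3]
        if cur in STOP_CODONS or cur not in CODON_TO_AA:
            continue
        lo = max(off, 3 * k)
        hi = min(off + len(site), 3 * k + 3)
        chars = [(p - 3 * k, pattern[p - off]) for p in range(lo, hi)]
        for c in AA_TO_CODONS[CODON_TO_AA[cur]]:
            if c != cur and not all(c[i] in IUPAC_SETS[ch] for i, ch in chars):
                return True
    return False


def insert_sites(orf: str, classification: SiteClassification,
                 microbiome) -> str:
    """Realise unwanted-only sites by synonymous changes.

    Conflict-free potential placements go in first; conflicted groups
    are resolved in ascending conflict complexity, choosing within a
    group by (newly covered unwanted hosts, site count weighted toward
    hosts with fewer existing sites, lexicographic site, smallest
    offset). An insertion that would create an irremovable
    wanted-recognised site is skipped.
    """
    seq = orf.upper()
    protein = translate(seq)
    targets = classification.unwanted_only
    if not targets:
        return seq
    avoid = classification.wanted_only | classification.shared
    occs = [o for o in find_occurrences(seq, targets, classification)
            if o.status == "potential"]
    # one placement per enzyme covers its hosts; a few extras add count
    # coverage. Capping the candidates per (site, strand) keeps the
    # greedy selection tractable on REBASE-scale repertoires.
    capped: list[SiteOccurrence] = []
    by_site: dict[tuple[str, str], int] = {}
    for o in sorted(occs, key=lambda o: (len(o.required_codon_changes),
                                         o.offset)):
        k = (o.site, o.strand)
        if by_site.get(k, 0) < 3:
            by_site[k] = by_site.get(k, 0) + 1
            capped.append(o)
    occs = capped
    occs.sort(key=lambda o: (len(o.conflict_set), len(o.site), o.site, o.offset))

    def coverage_state(s: str) -> tuple[set[str], dict[str, int]]:
        covered: set[str] = set()
        counts: dict[str, int] = {}
        for site in targets:
            present = _present_matches(s, site.upper())
            if not present:
                continue
            _, un = classification.recognizers.get(site.upper(), (set(), set()))
            for hid in un:
                covered.add(hid)
                counts[hid] = counts.get(hid, 0) + len(present)
        return covered, counts

    applied_intervals: list[tuple[int, int]] = []
    used_codons: set[int] = set()
    i = 0
    while i < len(occs):
        level = len(occs[i].conflict_set)
        group = [o for o in occs[i:] if len(o.conflict_set) == level]
        i += len(group)
        remaining = list(group)
        while remaining:
            covered, counts = coverage_state(seq)
            best = None
            for o in remaining:
                if set(range(o.codon_span[0], o.codon_span[1] + 1)) & used_codons:
                    continue
                pattern = o.site if o.strand == "+" else reverse_complement(o.site)
                changes = _realize_at(seq, pattern, o.offset)
                if changes is None or not changes:
                    continue
                new_cov = len(o.recognizers_unwanted - covered)
                weight = sum(1.0 / (1 + counts.get(h, 0))
                             for h in o.recognizers_unwanted)
                key = (-new_cov, -weight, o.site, o.offset)
                if best is None or key < best[0]:
                    best = (key, o, changes)
            if best is None:
                break
            _, o, changes = best
            remaining.remove(o)
            cand = _apply_changes(seq, changes)
            # refuse edits that destroy any already-present unwanted-only
            # occurrence (keeps insertion monotone, hence idempotent)
            if not set(_present_sites(seq, targets)) <= \
                    set(_present_sites(cand, targets)):
                continue
            # refuse edits creating an irremovable wanted-recognised site
            prior = set(_present_sites(seq, avoid))
            created = [k for k in _present_sites(cand, avoid) if k not in prior]
            keep = applied_intervals + [o.interval]
            if any(not _removable_keeping(cand, k, keep, avoid) for k in created):
                continue
            seq = cand
            applied_intervals.append(o.interval)
            used_codons.update(range(o.codon_span[0], o.codon_span[1] + 1))
    assert translate(seq) == protein
    return seq


# ---------------------------------------------------------------------------
# removal


def remove_wanted_sites(orf: str, classification: SiteClassification,
                        wanted_logw: np.ndarray | None = None,
                        protect_intervals: list[tuple[int, int]] | None = None,
                        max_passes: int = 10,
                        ) -> tuple[str, list[SiteOccurrence]]:
    """Eliminate wanted-recognised site occurrences by synonymous changes.

    Each occurrence is broken with the fewest codon changes available,
    preferring the variant that least perturbs the wanted-host codon
    adaptation (``wanted_logw``: mean wanted-host log-weights indexed by
    sense codon). Occurrences forced by the amino-acid sequence and site
    ambiguity are returned as irremovable. Removal never re-creates a
    previously removed occurrence, and avoids destroying unwanted-only
    sites unless no alternative exists (logged).
    """
    seq = orf.upper()
    protein = translate(seq)
    avoid = classification.wanted_only | classification.shared
    unwanted_sites = classification.unwanted_only
    if not avoid:
        return seq, []
    removed_keys: set[tuple[str, int, str]] = set()
    irremovable: dict[tuple[str, int, str], SiteOccurrence] = {}

    def cub_cost(k: int, new_codon: str) -> float:
        if wanted_logw is None:
            return 0.0
        cur = seq[3 * k:3 * k + 3]
        return abs(wanted_logw[CODON_INDEX[new_codon]]
                   - wanted_logw[CODON_INDEX[cur]])

    for _ in range(max_passes):
        hits = sorted(set(_present_sites(seq, avoid)),
                      key=lambda t: (t[1], t[0], t[2]))
        hits = [h for h in hits if h not in irremovable]
        if not hits:
            break
        progress = False
        for site, off, strand in hits:
            if (site, off, strand) in irremovable:
                continue
            pattern = site if strand == "+" else reverse_complement(site)
            if not all(seq[off + i] in IUPAC_SETS[ch]
                       for i, ch in enumerate(pattern)):
                continue  # already broken by an earlier edit this pass
            k0, k1 = off // 3, (off + len(site) - 1) // 3
            span = range(k0, k1 + 1)
            fams = []
            editable = []
            for k in span:
                cur = seq[3 * k:3 * k + 3]
                if cur in STOP_CODONS or cur not in CODON_TO_AA:
                    fams.append([cur])
                else:
                    fams.append(list(AA_TO_CODONS[CODON_TO_AA[cur]]))
                    editable.append(k)
            unwanted_before = len(_present_sites(seq, unwanted_sites)) \
                if unwanted_sites else 0
            candidates = []
            fallback = []

            def consider(changes: list[tuple[int, str]]) -> None:
                cand = _apply_changes(seq, changes)
                if all(cand[off + i] in IUPAC_SETS[ch]
                       for i, ch in enumerate(pattern)):
                    return  # still matches
                # must not re-create a removed occurrence or add wanted sites
                new_wanted = set(_present_sites(cand, avoid))
                old_wanted = set(_present_sites(seq, avoid))
                added = new_wanted - old_wanted
                if added & removed_keys or added:
                    return
                cost = sum(cub_cost(k, c) for k, c in changes)
                entry = (len(changes), cost, changes)
                if unwanted_sites and \
                        len(_present_sites(cand, unwanted_sites)) < unwanted_before:
                    fallback.append(entry)
                else:
                    candidates.append(entry)

            # try single-codon escapes first, then pairs (minimal-change search)
            for k in editable:
                cur = seq[3 * k:3 * k + 3]
                for c in AA_TO_CODONS[CODON_TO_AA[cur]]:
                    if c != cur:
                        consider([(k, c)])
            if not candidates and not fallback and len(editable) >= 2:
                n_tried = 0
                for ii, ka in enumerate(editable):
                    cura = seq[3 * ka:3 * ka + 3]
                    for kb in editable[ii + 1:]:
                        curb = seq[3 * kb:3 * kb + 3]
                        for ca in AA_TO_CODONS[CODON_TO_AA[cura]]:
                            for cb in AA_TO_CODONS[CODON_TO_AA[curb]]:
                                if ca != cura and cb != curb:
                                    consider([(ka, ca), (kb, cb)])
                                    n_tried += 1
                                    if candidates or n_tried >= 400:
                                        break
                            if candidates or n_tried >= 400:
                                break
                        if candidates or n_tried >= 400:
                            break
                    if candidates or n_tried >= 400:
                        break
            pool = candidates or fallback
            if not pool:
                wa, un = classification.recognizers.get(site, (set(), set()))
                irremovable[(site, off, strand)] = SiteOccurrence(
                    site=site, offset=off, strand=strand, status="present",
                    recognizers_wanted=set(wa), recognizers_unwanted=set(un))
                continue
            if pool is fallback:
                log.warning("removing %s@%d sacrifices an unwanted-host site",
                            site, off)
            pool.sort(key=lambda e: (e[0], e[1],
                                     tuple(c for _, c in e[2])))
            _, _, changes = pool[0]
            seq = _apply_changes(seq, changes)
            removed_keys.add((site, off, strand))
            progress = True
        if not progress:
            break
    # anything still present and not yet reported is irremovable in context
    for key in set(_present_sites(seq, avoid)):
        if key not in irremovable:
            site, off, strand = key
            wa, un = classification.recognizers.get(site, (set(), set()))
            irremovable[key] = SiteOccurrence(
                site=site, offset=off, strand=strand, status="present",
                recognizers_wanted=set(wa), recognizers_unwanted=set(un))
    assert translate(seq) == protein
    return seq, sorted(irremovable.values(), key=lambda o: (o.offset, o.site))


# ---------------------------------------------------------------------------
# full pass


@dataclass
class SiteEditReport:
    classification: SiteClassification
    irremovable: list[SiteOccurrence]
    wanted_hosts_with_site: set[str]
    unwanted_hosts_with_site: set[str]
    unwanted_occurrences_before: int
    unwanted_occurrences_after: int


def edit_sites(orf: str, microbiome,
               wanted_logw: np.ndarray | None = None,
               ) -> tuple[str, SiteEditReport]:
    """Insert unwanted-only sites, then remove wanted-recognised sites.

    The insert/remove pair is iterated to a fixed point (removal edits
    can expose fresh insertable placements, and vice versa), so running
    the editor on its own output changes nothing.
    """
    classification = classify_sites(microbiome)
    before = len(_present_sites(orf.upper(), classification.unwanted_only))
    seq = orf.upper()
    irremovable: list[SiteOccurrence] = []
    for _ in range(6):
        prev = seq
        seq = insert_sites(seq, classification, microbiome)
        seq, irremovable = remove_wanted_sites(seq, classification,
                                               wanted_logw=wanted_logw)
        if seq == prev:
            break
    after = len(_present_sites(seq, classification.unwanted_only))
    wanted_hosts, unwanted_hosts = hosts_with_site(seq, microbiome)
    report = SiteEditReport(classification=classification,
                            irremovable=irremovable,
                            wanted_hosts_with_site=wanted_hosts,
                            unwanted_hosts_with_site=unwanted_hosts,
                            unwanted_occurrences_before=before,
                            unwanted_occurrences_after=after)
    return seq, report
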