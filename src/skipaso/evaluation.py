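"""Candidate-ASO evaluation: physicochemical profile, melting temperature,
genome specificity and the selection filters.

Morpholino design guidelines bound the candidate space: GC content within
40-60%, at most 36% G, no run of four or more consecutive Gs, and limited
self-complementarity (at most 16 contiguous base pairs).  Melting
temperature is computed three ways (basic, salt-adjusted, nearest-neighbor)
for reporting; no Tm threshold is applied by default.  Specificity requires
a unique ungapped match of the 25-mer target in the genome when up to two
mismatches are tolerated, on either strand.

Self-complementarity of a short oligo is dominated by the dimer of two
copies of the molecule: an intramolecular hairpin in a 25-mer cannot exceed
12 base pairs, so only the self-dimer can reach the 16-pair limit.  The
metric used is the longest contiguous complementary stretch (Watson-Crick
plus G-U wobble) over all antiparallel alignments of the sequence against
itself, additionally bounded below by the longest helix of the predicted
minimum-free-energy fold when the ViennaRNA bindings are importable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt
from numpy.lib.stride_tricks import sliding_window_view

from .constants import (GAS_CONSTANT, GC_MAX, GC_MIN, G_MAX, MAX_G_RUN,
                        MAX_SELF_COMP, MISMATCH_BUDGET, NA_CONC_M,
                        PRIMER_CONC_M, REQUIRED_GENOME_MATCHES)

try:  # optional folding engine for the intramolecular component
    import RNA as _vienna
except ImportError:  # pragma: no cover - depends on environment
    _vienna = None

RNA_ALPHABET = set("ACGU")

# antiparallel pairing partners, wobble included (RNA context)
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
          ("G", "U"), ("U", "G")}
_HBONDS = {("A", "U"): 2, ("U", "A"): 2, ("G", "C"): 3, ("C", "G"): 3,
           ("G", "U"): 2, ("U", "G"): 2}


@dataclass(frozen=True)
class PhysChemProfile:
    gc_percent: float
    g_percent: float
    max_g_run: int
    max_self_comp_pairs: int
    tm_basic: float
    tm_salt: float
    tm_nn: float


@dataclass(frozen=True)
class FilterThresholds:
    gc_min: float = GC_MIN
    gc_max: float = GC_MAX
    g_max: float = G_MAX
    max_g_run: int = MAX_G_RUN
    max_self_comp: int = MAX_SELF_COMP
    mismatch_budget: int = MISMATCH_BUDGET
    required_genome_matches: int = REQUIRED_GENOME_MATCHES
    tm_min: float | None = None  # optional; no default Tm criterion
    tm_max: float | None = None


@dataclass
class SpecificityResult:
    match_count: int
    locations: list[tuple[str, int, str, int]] = field(default_factory=list)
    unique: bool = False


@dataclass
class FilterReport:
    passed: bool
    failed_criteria: list[str]
    profile: PhysChemProfile
    specificity: SpecificityResult | None = None  # None = not evaluated


def _validate_rna(seq: str) -> str:
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in RNA_ALPHABET:
            raise ValueError(
                f"invalid character {c!r} at position {i + 1}; "
                "sequence must be RNA over A/C/G/U")
    return s


def _max_run(seq: str, char: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == char else 0
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# self-complementarity
# ---------------------------------------------------------------------------

def self_dimer_max(seq: str, mode: str = "pairs") -> int:
    """Longest contiguous complementary stretch in any self-dimer register.

    Two copies of the molecule are aligned antiparallel; position ``i`` of
    one copy faces position ``j`` of the other whenever ``i + j`` is
    constant for the register.  ``mode="pairs"`` counts base pairs in the
    longest contiguous stretch; ``mode="hbonds"`` sums hydrogen bonds
    (A-U 2, G-C 3, G-U 2) over that stretch instead.
    """
    s = _validate_rna(seq)
    n = len(s)
    best = 0
    for total in range(2 * n - 1):
        run = 0
        for i in range(max(0, total - n + 1), min(n, total + 1)):
            j = total - i
            pair = (s[i], s[j])
            if pair in _PAIRS:
                run += 1 if mode == "pairs" else _HBONDS[pair]
                best = max(best, run)
            else:
                run = 0
    return best


def _longest_fold_helix(seq: str) -> int:
    """Longest stacked helix in the MFE fold (0 without a folding engine)."""
    if _vienna is None:
        return 0
    structure, _ = _vienna.fold(seq)
    # pair table from dot-bracket
    stack: list[int] = []
    partner = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    best = run = 0
    prev = None
    for i, c in enumerate(structure):
        if c == "(":
            run = run + 1 if (prev is not None
                              and partner[i] == partner[prev] - 1) else 1
            best = max(best, run)
            prev = i
        else:
            if c == ")":
                prev = None
            # '.' between two '(' also breaks stacking via partner check
    return best


def max_self_complementarity(seq: str, mode: str = "pairs") -> int:
    dimer = self_dimer_max(seq, mode=mode)
    if mode == "pairs":
        return max(dimer, _longest_fold_helix(seq))
    return dimer


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

NN_TABLES = {"dna": _mt.DNA_NN2,  # Sugimoto 1996
             "rna": _mt.RNA_NN2}  # Xia 1998

_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")


def _nn_sums(seq_dna: str, table: dict) -> tuple[float, float]:
    """Stacked nearest-neighbor (ΔH kcal/mol, ΔS cal/mol/K) magnitude sums."""
    dh = ds = 0.0
    for i in range(len(seq_dna) - 1):
        d = seq_dna[i:i + 2]
        key = f"{d}/{d.translate(_COMPLEMENT_DNA)}"
        if key not in table:
            rc = d.translate(_COMPLEMENT_DNA)[::-1]
            key = f"{rc}/{rc.translate(_COMPLEMENT_DNA)}"
        h, s = table[key]
        dh += h
        ds += s
    return -dh, -ds


def compute_tm(sequence: str, method: str = "basic",
               na_conc: float = NA_CONC_M,
               primer_conc: float = PRIMER_CONC_M,
               nn_table: str = "rna") -> float:
    """Melting temperature (deg C) of an oligo by one of three methods.

    basic
        64.9 + 41*(G+C - 16.4)/N; concentration-independent.
    salt_adjusted
        100.5 + 41*(G+C)/N - 820/N + 16.6*log10([Na+]).
    nearest_neighbor
        (ΔH - 3.4 kcal/mol) / (ΔS + R*ln(1/[oligo])) + 16.6*log10([Na+]),
        with stacked ΔH/ΔS summed from the selected nearest-neighbor
        table (``"dna"``: Sugimoto 1996; ``"rna"``: Xia 1998) and the
        result converted from kelvin.  Assumes a non-self-complementary
        sequence containing at least one G or C.
    """
    s = _validate_rna(sequence)
    n = len(s)
    if n < 2:
        raise ValueError("sequence must be at least 2 nt")
    gc = s.count("G") + s.count("C")
    if method == "basic":
        return 64.9 + 41.0 * (gc - 16.4) / n
    if method == "salt_adjusted":
        return (100.5 + 41.0 * gc / n - 820.0 / n
                + 16.6 * math.log10(na_conc))
    if method == "nearest_neighbor":
        if gc == 0:
            raise ValueError(
                "nearest-neighbor method requires at least one G or C")
        table = NN_TABLES[nn_table]
        seq_dna = s.replace("U", "T")
        dh, ds = _nn_sums(seq_dna, table)
        tm_k = (dh * 1000.0 - 3400.0) / (
            ds + GAS_CONSTANT * math.log(1.0 / primer_conc))
        return tm_k - 273.15 + 16.6 * math.log10(na_conc)
    raise ValueError(f"unknown Tm method {method!r}")


# ---------------------------------------------------------------------------
# physicochemical profile
# ---------------------------------------------------------------------------

def compute_physchem(aso_sequence: str,
                     na_conc: float = NA_CONC_M,
                     primer_conc: float = PRIMER_CONC_M,
                     nn_table: str = "rna") -> PhysChemProfile:
    s = _validate_rna(aso_sequence)
    if len(s) < 2:
        raise ValueError("sequence must be at least 2 nt")
    n = len(s)
    gc = s.count("G") + s.count("C")
    g = s.count("G")
    return PhysChemProfile(
        gc_percent=100.0 * gc / n,
        g_percent=100.0 * g / n,
        max_g_run=_max_run(s, "G"),
        max_self_comp_pairs=max_self_complementarity(s),
        tm_basic=compute_tm(s, "basic"),
        tm_salt=compute_tm(s, "salt_adjusted", na_conc=na_conc),
        tm_nn=(compute_tm(s, "nearest_neighbor", na_conc=na_conc,
                          primer_conc=primer_conc, nn_table=nn_table)
               if g + s.count("C") > 0 else float("nan")),
    )


# ---------------------------------------------------------------------------
# genome specificity
# ---------------------------------------------------------------------------

def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(Path(genome)), "fasta")}


def _scan_strand(chrom_seq: np.ndarray, query: np.ndarray,
                 budget: int) -> list[tuple[int, int]]:
    if len(chrom_seq) < len(query):
        return []
    windows = sliding_window_view(chrom_seq, len(query))
    mism = (windows != query).sum(axis=1)
    hits = np.nonzero(mism <= budget)[0]
    return [(int(p), int(mism[p])) for p in hits]


def search_genome_matches(aso_sequence: str, genome,
                          mismatch_budget: int = MISMATCH_BUDGET,
                          required_matches: int = REQUIRED_GENOME_MATCHES
                          ) -> SpecificityResult:
    """All ungapped genome alignments of the ASO target within a mismatch
    budget, on both strands.

    The ASO (RNA, antisense) is converted to its DNA target sense sequence
    and slid along each chromosome and its reverse complement; an
    alignment with at most ``mismatch_budget`` mismatches counts as a
    binding site.  ``unique`` is true when the total equals
    ``required_matches`` (1: the on-target site only).
    """
    s = _validate_rna(aso_sequence)
    chroms = _load_genome(genome)
    if not chroms or all(len(v) == 0 for v in chroms.values()):
        raise ValueError("empty genome")
    target = str(Seq(s.replace("U", "T")).reverse_complement())
    fwd = np.frombuffer(target.encode(), dtype=np.uint8)
    rev = np.frombuffer(str(Seq(target).reverse_complement()).encode(),
                        dtype=np.uint8)
    locations: list[tuple[str, int, str, int]] = []
    for chrom, seq in chroms.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for pos, mm in _scan_strand(arr, fwd, mismatch_budget):
            locations.append((chrom, pos, "+", mm))
        for pos, mm in _scan_strand(arr, rev, mismatch_budget):
            locations.append((chrom, pos, "-", mm))
    locations.sort()
    return SpecificityResult(match_count=len(locations),
                             locations=locations,
                             unique=len(locations) == required_matches)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(aso_sequence: str,
                  thresholds: FilterThresholds | None = None,
                  genome=None,
                  profile: PhysChemProfile | None = None) -> FilterReport:
    """Pass/fail verdict for one candidate against all selection criteria.

    Without a genome, specificity is skipped and flagged not-evaluated
    (``specificity is None`` in the report); it then neither passes nor
    fails the candidate.
    """
    th = thresholds or FilterThresholds()
    prof = profile or compute_physchem(aso_sequence)
    failed: list[str] = []
    if not (th.gc_min <= prof.gc_percent <= th.gc_max):
        failed.append("gc_range")
    if prof.g_percent > th.g_max:
        failed.append("g_content")
    if prof.max_g_run > th.max_g_run:
        failed.append("g_run")
    if prof.max_self_comp_pairs > th.max_self_comp:
        failed.append("self_complementarity")
    if th.tm_min is not None and prof.tm_basic < th.tm_min:
        failed.append("tm_low")
    if th.tm_max is not None and prof.tm_basic > th.tm_max:
        failed.append("tm_high")
    spec = None
    if genome is not None:
        spec = search_genome_matches(
            aso_sequence, genome, mismatch_budget=th.mismatch_budget,
            required_matches=th.required_genome_matches)
        if not spec.unique:
            failed.append("specificity")
    return FilterReport(passed=not failed, failed_criteria=failed,
                        profile=prof, specificity=spec)
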