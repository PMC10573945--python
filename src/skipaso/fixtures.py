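"""Deterministic synthetic loci, mutation tables and mini-genomes.

Real inputs to the pipeline are a GENCODE annotation, a genome, a COSMIC
mutation export and a SpliceAid enhancer table.  This module generates
small stand-ins for all four from a declarative :class:`LocusSpec`:
single-chromosome genomes carrying one gene with canonical GT..AG introns,
GENCODE-attribute GFF3, COSMIC-vocabulary mutation TSVs with planted
per-exon patient hotspots, and an enhancer motif table with planted
occurrences.  The same seed always yields byte-identical files.

Three families of shipped specs exercise every pipeline branch:

* :func:`nras_like_spec` -- a 7-exon oncogene-patterned locus (CDS in
  exons 2-5) whose two internal fully coding exons are frame-shifting;
  the donor-junction context of its third exon embeds the sequence
  implied by the NRAS exon-3 reference candidate set, so junction design
  regenerates those 25-mers verbatim.
* :func:`vhl_like_spec` -- a tumor-suppressor-patterned locus with two
  transcripts sharing a frame-preserving second exon whose acceptor and
  donor contexts embed the VHL exon-2 reference set.
* :func:`nmd_branch_spec` -- minimal 5-exon loci crafted so that
  skipping the middle exon drives the transcript into one chosen
  outcome: in-frame, degraded, each NMD-evasion rule, or nonstop.
  Crafted exons use a poly-C body (no stop codon in any frame) with the
  start codon, annotated stop and the premature stop planted explicitly.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .design import EseMotif

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TranscriptSpec:
    """One transcript over the locus exon chain (1-based exon indices)."""

    id: str
    exon_indices: tuple[int, ...]
    start_exon: int   # exon-chain index containing the start codon
    start_offset: int  # 0-based offset of the A of ATG within that exon
    stop_exon: int
    stop_offset: int   # 0-based offset of the first base of the stop codon


@dataclass(frozen=True)
class Patch:
    """Fixed subsequence written into an exon (negative offset = from end)."""

    exon_index: int
    offset: int
    sequence: str


@dataclass(frozen=True)
class IntronPatch:
    intron_index: int  # 1-based: intron i follows exon i
    offset: int
    sequence: str


@dataclass(frozen=True)
class Hotspot:
    """``n_samples`` distinct patients mutated at one exonic position."""

    exon_index: int
    offset: int
    n_samples: int
    description: str = "Substitution - Missense"


@dataclass
class LocusSpec:
    seed: int
    gene: str
    chrom: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    transcripts: list[TranscriptSpec]
    exon_sequences: dict[int, str] = field(default_factory=dict)
    exon_patches: list[Patch] = field(default_factory=list)
    intron_sequences: dict[int, str] = field(default_factory=dict)
    intron_patches: list[IntronPatch] = field(default_factory=list)
    planted_ese: list[tuple[int, int, str]] = field(default_factory=list)
    ese_motifs: list[EseMotif] = field(default_factory=list)
    hotspots: list[Hotspot] = field(default_factory=list)
    class_mix: dict[str, int] = field(default_factory=dict)
    flank: int = 300
    exon_ids: dict[int, str] = field(default_factory=dict)

    def exon_id(self, index: int) -> str:
        return self.exon_ids.get(index, f"{self.gene}.E{index:02d}")


@dataclass
class Locus:
    spec: LocusSpec
    genome: dict[str, str]
    gff3_text: str
    fasta_text: str
    exon_genomic_starts: list[int]  # 0-based, per exon-chain index
    gene_start: int
    gene_end: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": out / f"{self.spec.gene}.gff3",
            "fasta": out / f"{self.spec.gene}.fa",
        }
        paths["gff3"].write_text(self.gff3_text)
        paths["fasta"].write_text(self.fasta_text)
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _write(arr: np.ndarray, offset: int, seq: str,
           locked: set[int]) -> None:
    for i, c in enumerate(seq):
        arr[offset + i] = ord(c)
        locked.add(offset + i)


def _validate_spec(spec: LocusSpec) -> None:
    n = len(spec.exon_lengths)
    if len(spec.intron_lengths) != n - 1:
        raise ValueError("need exactly one intron between consecutive exons")
    if any(length <= 0 for length in spec.exon_lengths + spec.intron_lengths):
        raise ValueError("exon and intron lengths must be positive")
    for ts in spec.transcripts:
        idx = list(ts.exon_indices)
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"{ts.id}: exon indices must be increasing")
        if any(not (1 <= i <= n) for i in idx):
            raise ValueError(f"{ts.id}: exon index out of range")
        if ts.start_exon not in idx or ts.stop_exon not in idx:
            raise ValueError(f"{ts.id}: start/stop exon not in transcript")
        if (ts.stop_exon, ts.stop_offset) <= (ts.start_exon, ts.start_offset):
            raise ValueError(f"{ts.id}: stop codon precedes start codon")
        if ts.stop_offset + 3 > spec.exon_lengths[ts.stop_exon - 1]:
            raise ValueError(f"{ts.id}: stop codon exceeds its exon")


def _cds_positions(spec: LocusSpec, ts: TranscriptSpec
                   ) -> list[tuple[int, int]]:
    """Ordered (exon_index, offset) pairs of every coding base (incl. stop)."""
    out: list[tuple[int, int]] = []
    in_cds = False
    for i in ts.exon_indices:
        length = spec.exon_lengths[i - 1]
        lo, hi = 0, length
        if i == ts.start_exon:
            lo = ts.start_offset
            in_cds = True
        if not in_cds:
            continue
        if i == ts.stop_exon:
            hi = ts.stop_offset + 3
        out.extend((i, off) for off in range(lo, hi))
        if i == ts.stop_exon:
            break
    return out


def generate_locus(spec: LocusSpec) -> Locus:
    """Emit the genome FASTA + GFF3 for one synthetic locus.

    Exon bodies are uniform-random unless overridden or patched; coding
    regions are then repaired so that the only in-frame stop of each
    transcript is its designated stop codon (a premature stop whose three
    bases are all pinned by overrides/patches is an authoring error and
    raises).
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    n = len(spec.exon_lengths)

    exon_arrs: list[np.ndarray] = []
    locked: list[set[int]] = []
    for i in range(1, n + 1):
        length = spec.exon_lengths[i - 1]
        lock: set[int] = set()
        if i in spec.exon_sequences:
            s = spec.exon_sequences[i].upper()
            if len(s) != length:
                raise ValueError(
                    f"exon {i} override is {len(s)} nt, expected {length}")
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            lock.update(range(length))
        else:
            arr = _random_seq(rng, length)
        exon_arrs.append(arr)
        locked.append(lock)

    intron_arrs: list[np.ndarray] = []
    for i in range(1, n):
        length = spec.intron_lengths[i - 1]
        if length < 4:
            raise ValueError("introns need >= 4 nt for GT..AG ends")
        if i in spec.intron_sequences:
            s = spec.intron_sequences[i].upper()
            if len(s) != length:
                raise ValueError(
                    f"intron {i} override is {len(s)} nt, expected {length}")
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        else:
            arr = _random_seq(rng, length)
            arr[0:2] = np.frombuffer(b"GT", dtype=np.uint8)
            arr[-2:] = np.frombuffer(b"AG", dtype=np.uint8)
        intron_arrs.append(arr)

    for p in spec.exon_patches:
        arr = exon_arrs[p.exon_index - 1]
        off = p.offset if p.offset >= 0 else len(arr) + p.offset
        if off < 0 or off + len(p.sequence) > len(arr):
            raise ValueError(f"patch exceeds exon {p.exon_index}")
        _write(arr, off, p.sequence.upper(), locked[p.exon_index - 1])
    for ip in spec.intron_patches:
        arr = intron_arrs[ip.intron_index - 1]
        off = ip.offset if ip.offset >= 0 else len(arr) + ip.offset
        if off < 0 or off + len(ip.sequence) > len(arr):
            raise ValueError(f"patch exceeds intron {ip.intron_index}")
        for k, c in enumerate(ip.sequence.upper()):
            arr[off + k] = ord(c)
    for exon_index, off, motif in spec.planted_ese:
        arr = exon_arrs[exon_index - 1]
        if off < 0 or off + len(motif) > len(arr):
            raise ValueError(f"planted ESE exceeds exon {exon_index}")
        _write(arr, off, motif.upper().replace("U", "T"),
               locked[exon_index - 1])

    # start / stop codons, then premature-stop repair, per transcript
    def base(pos: tuple[int, int]) -> str:
        return chr(exon_arrs[pos[0] - 1][pos[1]])

    for ts in spec.transcripts:
        for codon, exon_i, off in (("ATG", ts.start_exon, ts.start_offset),
                                   ("TAA", ts.stop_exon, ts.stop_offset)):
            arr, lock = exon_arrs[exon_i - 1], locked[exon_i - 1]
            pinned = [off + k in lock for k in range(3)]
            if all(pinned):
                found = _to_str(arr[off:off + 3])
                ok = found == codon or (codon == "TAA" and found in STOPS)
                if not ok:
                    raise ValueError(
                        f"{ts.id}: overridden exon {exon_i} lacks the "
                        f"declared {codon} at offset {off} (found {found})")
            else:
                _write(arr, off, codon, lock)

    for ts in spec.transcripts:
        positions = _cds_positions(spec, ts)
        if len(positions) % 3:
            raise ValueError(
                f"{ts.id}: CDS length {len(positions)} not divisible by 3")
        for c in range(0, len(positions) - 3, 3):  # excludes the stop codon
            triplet = positions[c:c + 3]
            codon = "".join(base(p) for p in triplet)
            if codon in STOPS:
                for exon_i, off in triplet:
                    if off not in locked[exon_i - 1]:
                        _write(exon_arrs[exon_i - 1], off, "C",
                               locked[exon_i - 1])
                        break
                else:
                    raise ValueError(
                        f"{ts.id}: premature stop {codon} pinned by "
                        f"overrides at CDS codon {c // 3}")

    # assemble the chromosome
    parts = [_random_seq(rng, spec.flank)]
    exon_starts: list[int] = []
    pos = spec.flank
    for i in range(n):
        exon_starts.append(pos)
        parts.append(exon_arrs[i])
        pos += len(exon_arrs[i])
        if i < n - 1:
            parts.append(intron_arrs[i])
            pos += len(intron_arrs[i])
    gene_end = pos
    parts.append(_random_seq(rng, spec.flank))
    genome_seq = _to_str(np.concatenate(parts))

    gff3 = _render_gff3(spec, exon_starts)
    fasta = _render_fasta(spec.chrom, genome_seq)
    return Locus(spec=spec, genome={spec.chrom: genome_seq},
                 gff3_text=gff3, fasta_text=fasta,
                 exon_genomic_starts=exon_starts,
                 gene_start=spec.flank, gene_end=gene_end)


def _render_fasta(chrom: str, seq: str, width: int = 70) -> str:
    lines = [f">{chrom}"]
    lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


def _render_gff3(spec: LocusSpec, exon_starts: list[int]) -> str:
    def exon_iv(i: int) -> tuple[int, int]:  # 1-based inclusive
        s = exon_starts[i - 1]
        return s + 1, s + spec.exon_lengths[i - 1]

    gene_id = f"gene:{spec.gene}"
    g_start = exon_iv(1)[0]
    g_end = max(exon_iv(ts.exon_indices[-1])[1] for ts in spec.transcripts)
    rows = ["##gff-version 3"]

    def row(ftype: str, start: int, end: int, attrs: str) -> None:
        rows.append("\t".join([spec.chrom, "skipaso", ftype, str(start),
                               str(end), ".", "+",
                               "0" if ftype == "CDS" else ".", attrs]))

    row("gene", g_start, g_end, f"ID={gene_id};gene_name={spec.gene}")
    for ts in spec.transcripts:
        t_start = exon_iv(ts.exon_indices[0])[0]
        t_end = exon_iv(ts.exon_indices[-1])[1]
        row("transcript", t_start, t_end,
            f"ID={ts.id};Parent={gene_id};gene_name={spec.gene};"
            "transcript_type=protein_coding")
        for rank, i in enumerate(ts.exon_indices, start=1):
            s, e = exon_iv(i)
            row("exon", s, e,
                f"ID=exon:{ts.id}:{rank};Parent={ts.id};"
                f"exon_id={spec.exon_id(i)};exon_number={rank}")
        # CDS features: coding portion of each exon between start and stop
        in_cds = False
        for i in ts.exon_indices:
            s, e = exon_iv(i)
            lo, hi = s, e
            if i == ts.start_exon:
                lo = s + ts.start_offset
                in_cds = True
            if not in_cds:
                continue
            if i == ts.stop_exon:
                hi = s + ts.stop_offset + 2
            row("CDS", lo, hi, f"ID=CDS:{ts.id};Parent={ts.id}")
            if i == ts.stop_exon:
                break
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# mutation table
# ---------------------------------------------------------------------------

def generate_mutation_table(locus: Locus) -> str:
    """COSMIC-style TSV from the spec's hotspots and class mix.

    Hotspot rows are single-base substitutions at the planted exonic
    position, one per distinct sample.  Class-mix rows (used to force a
    20/20 label) are placed at intronic positions inside the gene body so
    that per-exon patient counts stay controlled solely by the hotspots.
    """
    spec = locus.spec
    lines = ["Gene name\tID_sample\tMutation Description\t"
             "Mutation genome position"]
    counter = 0
    for h in spec.hotspots:
        if not (1 <= h.exon_index <= len(spec.exon_lengths)):
            raise ValueError(f"hotspot exon {h.exon_index} out of range")
        if not (0 <= h.offset < spec.exon_lengths[h.exon_index - 1]):
            raise ValueError(
                f"hotspot offset {h.offset} outside exon {h.exon_index}")
        pos1 = locus.exon_genomic_starts[h.exon_index - 1] + h.offset + 1
        for _ in range(h.n_samples):
            counter += 1
            lines.append(f"{spec.gene}\tS{counter:05d}\t{h.description}\t"
                         f"{spec.chrom}:{pos1}-{pos1}")
    if spec.class_mix:
        intron_pos: list[int] = []
        for i in range(len(spec.exon_lengths) - 1):
            s = (locus.exon_genomic_starts[i]
                 + spec.exon_lengths[i])
            intron_pos.extend(range(s + 3, s + spec.intron_lengths[i] - 3))
        if not intron_pos:
            raise ValueError("class mix needs at least one intron")
        k = 0
        for desc in sorted(spec.class_mix):
            for _ in range(spec.class_mix[desc]):
                counter += 1
                pos1 = intron_pos[k % len(intron_pos)] + 1
                k += 1
                lines.append(f"{spec.gene}\tS{counter:05d}\t{desc}\t"
                             f"{spec.chrom}:{pos1}-{pos1}")
    return "\n".join(lines) + "\n"


def write_ese_table(spec: LocusSpec, path: str | Path) -> Path:
    path = Path(path)
    lines = ["motif\tprotein\tscore"]
    lines.extend(f"{m.motif}\t{m.protein}\t{m.score}"
                 for m in spec.ese_motifs)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# off-target planting
# ---------------------------------------------------------------------------

def plant_offtarget(locus: Locus, target_window: str, k_mismatches: int,
                    seed: int) -> Locus:
    """Copy the 25-mer target into the 3' flank with exactly k mismatches."""
    target = target_window.upper().replace("U", "T")
    if not (0 <= k_mismatches <= len(target)):
        raise ValueError("k_mismatches out of range")
    chrom = locus.spec.chrom
    seq = locus.genome[chrom]
    room = len(seq) - locus.gene_end - len(target) - 10
    if room <= 0:
        raise ValueError("no room outside the gene body to plant a site")
    rng = np.random.default_rng(seed)
    pos = locus.gene_end + 10 + int(rng.integers(0, room))
    copy_arr = list(target)
    sites = rng.choice(len(target), size=k_mismatches, replace=False)
    for i in sorted(int(s) for s in sites):
        alternatives = [b for b in "ACGT" if b != copy_arr[i]]
        copy_arr[i] = alternatives[int(rng.integers(0, 3))]
    new_seq = seq[:pos] + "".join(copy_arr) + seq[pos + len(target):]
    new = copy.copy(locus)
    new.genome = {chrom: new_seq}
    new.fasta_text = _render_fasta(chrom, new_seq)
    return new


# ---------------------------------------------------------------------------
# reference-derived junction contexts
# ---------------------------------------------------------------------------

def _target_dna(aso_rna: str) -> str:
    """Sense DNA target window of an antisense RNA 25-mer."""
    return str(Seq(aso_rna.replace("U", "T")).reverse_complement())


DEFAULT_ESE_MOTIFS = [
    EseMotif("GAAGAA", "SF2/ASF", 5),
    EseMotif("TGGAAGA", "9G8", 4),
    EseMotif("CACACGA", "SRp20", 3),
    EseMotif("TAGGGT", "hnRNP A1", -8),  # silencer: must be ignored
]


def nras_like_spec(seed: int = 7) -> LocusSpec:
    """Oncogene-patterned 7-exon locus, CDS in exons 2-5.

    Exons 3 (103 nt) and 4 (160 nt) are the internal fully coding exons;
    both are frame-shifting.  The end of exon 3 and the start of its
    downstream intron carry the donor-junction context implied by the
    NRAS exon-3 reference candidates, so the donor design set reproduces
    those sequences.  Exon 3 concentrates missense hotspots, giving the
    gene an oncogene 20/20 pattern.
    """
    from .reference import NRAS_EXON3_JUNCTION_ASOS

    t = _target_dna(NRAS_EXON3_JUNCTION_ASOS["H3D (13, -12)"])
    exon3_tail = t[:13]
    t8 = _target_dna(NRAS_EXON3_JUNCTION_ASOS["H3D (8, -17)"])
    intron3_head = t8[8:]
    return LocusSpec(
        seed=seed, gene="NRASL", chrom="chrN",
        exon_lengths=[80, 120, 103, 160, 150, 90, 200],
        intron_lengths=[90, 80, 70, 85, 75, 95],
        transcripts=[TranscriptSpec(
            id="NRASL-201", exon_indices=(1, 2, 3, 4, 5, 6, 7),
            start_exon=2, start_offset=39, stop_exon=5, stop_offset=49)],
        exon_patches=[Patch(3, -13, exon3_tail)],
        intron_patches=[IntronPatch(3, 0, intron3_head)],
        planted_ese=[(3, 30, "GAAGAA"), (3, 55, "GAAGAA"),
                     (4, 40, "GAAGAA"), (4, 90, "CACACGA")],
        ese_motifs=DEFAULT_ESE_MOTIFS,
        hotspots=[Hotspot(3, 20, 60), Hotspot(4, 33, 25), Hotspot(2, 50, 10)],
        class_mix={"Substitution - coding silent": 5,
                   "Deletion - Frameshift": 2},
    )


def vhl_like_spec(seed: int = 11) -> LocusSpec:
    """Tumor-suppressor-patterned locus; two transcripts share exon 2.

    Exon 2 (123 nt) preserves the frame when skipped.  Its acceptor and
    donor junction contexts embed the sequences implied by the VHL
    exon-2 reference candidates, so the full 14-candidate junction set is
    regenerated verbatim.  Nonsense hotspots give the gene a
    tumor-suppressor 20/20 pattern.
    """
    from .reference import VHL_EXON2_JUNCTION_ASOS

    acc = _target_dna(VHL_EXON2_JUNCTION_ASOS["H2A (-18, 7)"])
    intron1_tail = acc[:18]
    exon2_head = _target_dna(VHL_EXON2_JUNCTION_ASOS["H2A (-12, 13)"])[12:]
    don = _target_dna(VHL_EXON2_JUNCTION_ASOS["H2D (13, -12)"])
    exon2_tail = don[:13]
    intron2_head = _target_dna(VHL_EXON2_JUNCTION_ASOS["H2D (7, -18)"])[7:]
    return LocusSpec(
        seed=seed, gene="VHLL", chrom="chrV",
        exon_lengths=[130, 123, 180, 160],
        intron_lengths=[100, 90, 80],
        transcripts=[
            TranscriptSpec(id="VHLL-201", exon_indices=(1, 2, 3),
                           start_exon=1, start_offset=30,
                           stop_exon=3, stop_offset=50),
            TranscriptSpec(id="VHLL-202", exon_indices=(1, 2, 4),
                           start_exon=1, start_offset=30,
                           stop_exon=4, stop_offset=50),
        ],
        exon_patches=[Patch(2, 0, exon2_head), Patch(2, -13, exon2_tail)],
        intron_patches=[IntronPatch(1, -18, intron1_tail),
                        IntronPatch(2, 0, intron2_head)],
        planted_ese=[(2, 40, "GAAGAA"), (2, 70, "GAAGAA"),
                     (2, 95, "CACACGA")],
        ese_motifs=DEFAULT_ESE_MOTIFS,
        hotspots=[Hotspot(2, 60, 45, "Substitution - Nonsense"),
                  Hotspot(1, 60, 30, "Substitution - Nonsense"),
                  Hotspot(3, 60, 20, "Substitution - Nonsense")],
        class_mix={"Substitution - coding silent": 200,
                   "Deletion - Frameshift": 40,
                   "Substitution - Missense": 30},
    )


NMD_BRANCHES = ("in_frame", "degraded", "last_exon", "fifty_five_nt",
                "start_proximal", "nonstop")


def nmd_branch_spec(branch: str, seed: int = 3) -> LocusSpec:
    """A 5-exon locus whose middle-exon skip lands in one chosen branch.

    Skipping exon 3 (100 nt, frame-shifting except for ``in_frame``)
    shifts the downstream frame; exon bodies are poly-C (stop-free in
    every frame) with the decisive premature stop planted at a position
    chosen relative to the 55-nt junction window, the 150-nt
    start-proximal window and the last exon.
    """
    if branch not in NMD_BRANCHES:
        raise ValueError(f"unknown branch {branch!r}; "
                         f"choose from {NMD_BRANCHES}")
    e1 = "C" * 30 + "ATG" + "C" * 27          # start codon at offset 30
    e2 = "C" * (30 if branch == "start_proximal" else 90)
    e3 = "C" * (99 if branch == "in_frame" else 100)
    e5 = "C" * 50 + "TAA" + "C" * 47          # annotated stop at offset 50
    if branch == "degraded":
        e4 = "C" * 33 + "TAA" + "C" * 114     # PTC >150 from start, >=55 from junction
    elif branch == "fifty_five_nt":
        e4 = "C" * 99 + "TAA" + "C" * 48      # PTC 51 nt upstream of last junction
    elif branch == "start_proximal":
        e4 = "C" * 30 + "TAA" + "C" * 117     # PTC 90 nt after the start codon
    else:  # in_frame, last_exon, nonstop: no stop inside exon 4
        e4 = "C" * (151 if branch == "in_frame" else 150)
    if branch == "last_exon":
        e5 = "C" * 12 + "TAA" + "C" * 35 + "TAA" + "C" * 47
    return LocusSpec(
        seed=seed, gene=f"NMD{branch.upper().replace('_', '')[:6]}",
        chrom="chrM1",
        exon_lengths=[len(e1), len(e2), len(e3), len(e4), len(e5)],
        intron_lengths=[40, 40, 40, 40],
        transcripts=[TranscriptSpec(
            id=f"NMD-{branch}", exon_indices=(1, 2, 3, 4, 5),
            start_exon=1, start_offset=30, stop_exon=5, stop_offset=50)],
        exon_sequences={1: e1, 2: e2, 3: e3, 4: e4, 5: e5},
        ese_motifs=DEFAULT_ESE_MOTIFS,
    )


SHIPPED_SPECS = {
    "nras-like": nras_like_spec,
    "vhl-like": vhl_like_spec,
    **{f"nmd-{b.replace('_', '-')}":
       (lambda seed=3, _b=b: nmd_branch_spec(_b, seed))
       for b in NMD_BRANCHES},
}


def with_seed(spec: LocusSpec, seed: int) -> LocusSpec:
    return replace(spec, seed=seed)
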