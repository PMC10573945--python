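"""Shared fixtures: synthetic loci generated once per session."""
from __future__ import annotations

from pathlib import Path

import pytest

from skipaso import fixtures as fx
from skipaso.annotation import load_gene_model


def _materialize(spec: fx.LocusSpec, out: Path) -> dict:
    locus = fx.generate_locus(spec)
    paths = locus.write(out)
    mut = out / f"{spec.gene}.mutations.tsv"
    mut.write_text(fx.generate_mutation_table(locus))
    ese = fx.write_ese_table(spec, out / f"{spec.gene}.ese.tsv")
    return {"locus": locus, "spec": spec, "mutations": mut, "ese": ese,
            **paths}


@pytest.fixture(scope="session")
def nras_fixture(tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("nras")
    return _materialize(fx.nras_like_spec(), out)


@pytest.fixture(scope="session")
def vhl_fixture(tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("vhl")
    return _materialize(fx.vhl_like_spec(), out)


@pytest.fixture(scope="session")
def nras_model(nras_fixture):
    return load_gene_model(nras_fixture["gff3"], nras_fixture["fasta"])


@pytest.fixture(scope="session")
def vhl_model(vhl_fixture):
    return load_gene_model(vhl_fixture["gff3"], vhl_fixture["fasta"])


def write_toy_locus(tmp: Path, strand: str = "+") -> tuple[Path, Path]:
    """Hand-built 1-gene / 1-transcript / 3-exon locus on a 60-nt genome.

    Exon coordinates (1-based GFF3): 5-10, 21-30, 41-52; CDS covers the
    middle exon plus parts of the flanking ones.
    """
    genome = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"[:60]
    fasta = tmp / "toy.fa"
    fasta.write_text(">chrT\n" + genome + "\n")
    gid, tid = "gene:TOY", "TOY-201"
    rows = ["##gff-version 3",
            f"chrT\ttest\tgene\t5\t52\t.\t{strand}\t.\tID={gid};gene_name=TOY",
            f"chrT\ttest\ttranscript\t5\t52\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid};gene_name=TOY;"
            "transcript_type=protein_coding"]
    for i, (s, e) in enumerate([(5, 10), (21, 30), (41, 52)], start=1):
        rows.append(f"chrT\ttest\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID=exon:{tid}:{i};Parent={tid};exon_id=TOY.E{i:02d};"
                    f"exon_number={i}")
    for s, e in [(8, 10), (21, 30), (41, 43)]:
        rows.append(f"chrT\ttest\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                    f"ID=CDS:{tid};Parent={tid}")
    gff3 = tmp / "toy.gff3"
    gff3.write_text("\n".join(rows) + "\n")
    return gff3, fasta
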