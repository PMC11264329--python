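"""File-format helpers: FASTA parents and pools, oligo manifests, QC reports."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cassette import OligoDesign
from .mutagenesis import (
    LibraryMember,
    MutationCountQC,
    ParentCDS,
    format_mutation_string,
    member_from_cds,
)


def read_parent_fasta(path) -> ParentCDS:
    """Read the first record of a FASTA file as a parent CDS."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return ParentCDS(id=rec.id, sequence=str(rec.seq).upper())


def write_member_fasta(members: Iterable[LibraryMember], path) -> None:
    records = [
        SeqRecord(Seq(m.cds), id=m.member_id, description="")
        for m in members
    ]
    SeqIO.write(records, str(path), "fasta")


def read_member_fasta(path, parent: ParentCDS) -> list[LibraryMember]:
    """Read an observed pool, deriving mutation lists against the parent."""
    return [
        member_from_cds(parent, str(rec.seq).upper(), rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_oligo_fasta(oligos: Iterable[OligoDesign], path) -> None:
    records = [
        SeqRecord(Seq(o.full_oligo), id=o.member_id, description="")
        for o in oligos
    ]
    SeqIO.write(records, str(path), "fasta")


def oligo_manifest(
    members: Sequence[LibraryMember], oligos: Sequence[OligoDesign]
) -> pd.DataFrame:
    by_id = {m.member_id: m for m in members}
    rows = []
    for o in oligos:
        m = by_id[o.member_id]
        rows.append(
            {
                "member_id": o.member_id,
                "mutations": format_mutation_string(m.mutations),
                "n_mutations": m.designed_mutation_count,
                "window": f"{o.window.start}-{o.window.end}",
                "variable_region": o.variable_region,
                "full_oligo": o.full_oligo,
                "recodings": ";".join(
                    f"{r.position}:{r.old_codon}>{r.new_codon}" for r in o.recodings
                ),
            }
        )
    return pd.DataFrame(rows)


def qc_report_frame(qc: MutationCountQC) -> pd.DataFrame:
    status = {}
    for mid in qc.matching:
        status[mid] = "matching"
    for mid in qc.fewer:
        status[mid] = "fewer"
    for mid in qc.more:
        status[mid] = "more"
    return pd.DataFrame(
        {
            "member_id": list(qc.counts),
            "n_mutations": [qc.counts[m] for m in qc.counts],
            "designed_count": qc.designed_count,
            "status": [status[m] for m in qc.counts],
            "template_swap_candidate": [m in set(qc.flagged) for m in qc.counts],
        }
    )
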