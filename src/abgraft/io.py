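"""File I/O helpers: FASTA sequences, sensorgram CSV tables."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .numbering import AntibodySequence


def read_fasta(
    path, chain_class: Optional[str] = None
) -> list[AntibodySequence]:
    """Read antibody sequences from FASTA.

    The chain class is taken from the second ``|``-separated header field
    when present (``>id|heavy|...``), else from ``chain_class``.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        cc = fields[1].strip() if len(fields) > 1 else chain_class
        if cc is None:
            raise ValueError(
                f"record {rec.id!r}: no chain class in header and none supplied"
            )
        out.append(AntibodySequence(fields[0].strip(), cc, str(rec.seq).upper()))
    return out


def write_fasta(path, seqs: Iterable[AntibodySequence], descriptions=None) -> None:
    records = []
    for i, s in enumerate(seqs):
        desc = descriptions[i] if descriptions else s.chain_class
        records.append(
            SeqRecord(Seq(s.residues), id=f"{s.id}|{desc}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def write_sensorgram_csv(path, sset) -> None:
    """Write a SensorgramSet as CSV: time column + one response column per
    concentration, concentrations (molar) in the header."""
    df = pd.DataFrame({"time_s": sset.times})
    for c, trace in zip(sset.concentrations, sset.responses):
        df[f"conc_{c:.6g}M"] = trace
    df.to_csv(path, index=False)


def read_sensorgram_csv(path, t_assoc: float):
    """Read the CSV format written by :func:`write_sensorgram_csv`."""
    from .kinetics import SensorgramSet

    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(float)
    concs, traces = [], []
    for col in df.columns:
        if col.startswith("conc_"):
            concs.append(float(col[len("conc_"):-1]))
            traces.append(df[col].to_numpy(float))
    return SensorgramSet(
        concentrations=concs,
        times=times,
        t_assoc=t_assoc,
        responses=np.asarray(traces),
    )
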