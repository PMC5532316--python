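"""Readers and writers for the text formats the pipeline exchanges.

Transcriptomes travel as FASTA plus a sidecar annotation TSV (or a single
FASTA with pipe-delimited ``transcript_id|gene_id|gene_name|biotype``
headers); probes as an Affymetrix-style tab file; expression matrices as
GCT or plain TSV; phenotype labels as CLS; drug-induced lncRNA sets as GMT.
Gene identifiers are treated as opaque strings throughout.

All writers emit deterministic byte streams for a fixed input: stable row
and column order and floats at six significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reannotation import (
    Biotype,
    ProbeRecord,
    ReannotationMap,
    ReannotationParams,
    TranscriptRecord,
)
from .signatures import DrugLncRNASet, InstanceRecord, InstanceSignature

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# transcriptome


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_transcriptome(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, with biotypes from a sidecar TSV.

    The annotation TSV needs columns transcript_id, gene_id, biotype (and
    optionally gene_name).  Without a sidecar, FASTA headers must carry
    pipe-delimited ``transcript_id|gene_id|gene_name|biotype`` fields.
    Records whose biotype is neither lncRNA nor protein_coding are dropped
    with a logged count; a FASTA record missing from the annotation is an
    error.
    """
    annot: dict[str, tuple[str, str, str]] = {}
    if annotation_path is not None:
        table = pd.read_csv(annotation_path, sep="\t", dtype=str)
        required = {"transcript_id", "gene_id", "biotype"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(
                f"annotation {annotation_path}: missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(table.itertuples(index=False), start=2):
            tid = row.transcript_id
            if tid in annot:
                raise ValueError(
                    f"annotation {annotation_path} line {lineno}: "
                    f"duplicate transcript_id {tid!r}"
                )
            name = getattr(row, "gene_name", "") or ""
            annot[tid] = (row.gene_id, name, row.biotype)

    records: list[TranscriptRecord] = []
    dropped = 0
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if annotation_path is not None:
            tid = rec.id
            if tid not in annot:
                raise ValueError(
                    f"transcript {tid!r} present in FASTA but absent from "
                    f"the annotation table"
                )
            gene_id, gene_name, biotype = annot[tid]
        else:
            parts = rec.id.split("|")
            if len(parts) != 4:
                raise ValueError(
                    f"FASTA header {rec.id!r}: expected 4 pipe-delimited "
                    f"fields transcript_id|gene_id|gene_name|biotype"
                )
            tid, gene_id, gene_name, biotype = parts
        if tid in seen:
            raise ValueError(f"duplicate transcript id {tid!r} in FASTA")
        seen.add(tid)
        try:
            bt = Biotype(biotype)
        except ValueError:
            dropped += 1
            continue
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene_id,
                biotype=bt,
                sequence=_normalize_seq(str(rec.seq)),
                gene_name=gene_name,
            )
        )
    if dropped:
        logger.info("dropped %d transcripts with other biotypes", dropped)
    return records


def write_transcriptome(
    transcripts: Sequence[TranscriptRecord],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    recs = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "gene_name": t.gene_name,
            "biotype": t.biotype.value,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probes


def read_probe_tab(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    probe_length: int = 25,
) -> list[ProbeRecord]:
    """Read an Affymetrix-style probe tab file.

    Default column names are ``probe_id``, ``probeset_id`` and ``sequence``;
    ``column_map`` renames them ({"probe_id": "Probe ID", ...}).  If no
    probe_id column exists but ``x`` / ``y`` coordinates do, the probe id is
    composed as ``probeset_id:x:y``.  Sequences of the wrong length raise
    with the offending probe id.
    """
    cmap = {"probe_id": "probe_id", "probeset_id": "probeset_id",
            "sequence": "sequence", "x": "x", "y": "y"}
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(table.columns)
    if cmap["sequence"] not in cols:
        raise ValueError(f"probe file {path}: no sequence column {cmap['sequence']!r}")

    probes: list[ProbeRecord] = []
    seen: set[str] = set()
    for record in table.to_dict("records"):
        get = lambda key: str(record[key]) if key in cols else ""
        probeset = get(cmap["probeset_id"])
        if cmap["probe_id"] in cols:
            pid = get(cmap["probe_id"])
        elif cmap["x"] in cols and cmap["y"] in cols:
            pid = f"{probeset}:{get(cmap['x'])}:{get(cmap['y'])}"
        else:
            raise ValueError(
                f"probe file {path}: need a probe_id column or x/y coordinates"
            )
        seq = _normalize_seq(get(cmap["sequence"]))
        if len(seq) != probe_length:
            raise ValueError(
                f"probe {pid!r}: sequence length {len(seq)} != {probe_length}"
            )
        if pid in seen:
            raise ValueError(f"duplicate probe id {pid!r}")
        seen.add(pid)
        probes.append(ProbeRecord(probe_id=pid, probeset_id=probeset, sequence=seq))
    return probes


def write_probe_tab(probes: Sequence[ProbeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"probe_id": p.probe_id, "probeset_id": p.probeset_id,
             "sequence": p.sequence}
            for p in probes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reannotation map


def write_reannotation_map(
    remap: ReannotationMap, path: str | Path, provenance_path: str | Path | None = None
) -> None:
    """TSV (gene_id, gene_name, n_probes, comma-joined probe_ids) plus a JSON
    provenance sidecar with the filter-stage counters and parameters."""
    rows = [
        {
            "gene_id": g,
            "gene_name": remap.gene_names.get(g, ""),
            "n_probes": len(ps),
            "probe_ids": ",".join(sorted(ps)),
        }
        for g, ps in sorted(remap.gene_to_probes.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "gene_name", "n_probes", "probe_ids"]).to_csv(
        path, sep="\t", index=False
    )
    if provenance_path is not None:
        payload = {
            "provenance": remap.provenance,
            "params": {
                "probe_length": remap.params.probe_length,
                "min_probes_per_gene": remap.params.min_probes_per_gene,
                "strand_mode": remap.params.strand_mode.value,
                "ambiguity_policy": remap.params.ambiguity_policy.value,
                "evalue_cutoff": remap.params.evalue_cutoff,
            },
        }
        Path(provenance_path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )


def read_reannotation_map(
    path: str | Path, params: ReannotationParams | None = None
) -> ReannotationMap:
    table = pd.read_csv(path, sep="\t", dtype=str)
    gene_to_probes = {
        row.gene_id: frozenset(row.probe_ids.split(","))
        for row in table.itertuples(index=False)
    }
    names = {
        row.gene_id: ("" if pd.isna(row.gene_name) else row.gene_name)
        for row in table.itertuples(index=False)
    }
    return ReannotationMap(
        gene_to_probes=gene_to_probes,
        params=params or ReannotationParams(),
        gene_names=names,
    )


# ---------------------------------------------------------------------------
# expression matrices, labels, instances


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a GCT (``#1.2`` header) or plain TSV expression matrix.

    Rows are genes/probes, columns samples, values log2 intensities.
    Duplicate row ids and GCT dimension mismatches are errors.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):
        with open(path) as fh:
            fh.readline()
            dims = fh.readline().split()
            n_rows, n_cols = int(dims[0]), int(dims[1])
            table = pd.read_csv(fh, sep="\t")
        table = table.set_index(table.columns[0])
        table = table.drop(columns=[table.columns[0]])  # Description
        if table.shape != (n_rows, n_cols):
            raise ValueError(
                f"GCT {path}: declared {n_rows}x{n_cols}, found "
                f"{table.shape[0]}x{table.shape[1]}"
            )
    else:
        table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dup[:5]}")
    table.index = table.index.astype(str)
    table.index.name = "gene_id"
    return table.astype(float)


def write_gct(expr: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in expr.iterrows():
            vals = "\t".join(_fmt(v) for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = out.index.name or "id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_cls(path: str | Path, samples: Sequence[str]) -> dict[str, int]:
    """Read a standard three-line CLS phenotype file with 0/1 classes.

    ``samples`` gives the column order of the companion expression matrix;
    the i-th label applies to the i-th sample.
    """
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 3:
        raise ValueError(f"CLS {path}: expected 3 lines, found {len(lines)}")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    if n_classes != 2:
        raise ValueError(f"CLS {path}: need exactly 2 classes, found {n_classes}")
    labels = [int(tok) for tok in lines[2].split()]
    if len(labels) != n_samples:
        raise ValueError(
            f"CLS {path}: declared {n_samples} samples, found {len(labels)} labels"
        )
    if len(samples) != n_samples:
        raise ValueError(
            f"CLS {path}: {n_samples} labels for {len(samples)} matrix samples"
        )
    if set(labels) - {0, 1}:
        raise ValueError(f"CLS {path}: labels must be 0/1")
    return dict(zip(map(str, samples), labels))


def write_cls(labels: Mapping[str, int], samples: Sequence[str], path: str | Path) -> None:
    vals = [str(labels[s]) for s in samples]
    with open(path, "w") as fh:
        fh.write(f"{len(samples)} 2 1\n")
        fh.write("# 0 1\n")
        fh.write(" ".join(vals) + "\n")


def read_instances(path: str | Path) -> list[InstanceRecord]:
    """Instance metadata TSV: instance_id, drug_name, treatment_samples,
    control_samples (the sample columns comma-joined)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"instance_id", "drug_name", "treatment_samples", "control_samples"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"instance table {path}: missing columns {sorted(missing)}")
    out = []
    for row in table.itertuples(index=False):
        out.append(
            InstanceRecord(
                instance_id=row.instance_id,
                drug_name=row.drug_name,
                treatment_samples=tuple(row.treatment_samples.split(",")),
                control_samples=tuple(row.control_samples.split(",")),
            )
        )
    return out


def write_instances(instances: Sequence[InstanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "instance_id": i.instance_id,
                "drug_name": i.drug_name,
                "treatment_samples": ",".join(i.treatment_samples),
                "control_samples": ",".join(i.control_samples),
            }
            for i in instances
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(sets: Sequence[DrugLncRNASet], path: str | Path) -> None:
    """Standard GMT: name TAB description TAB members...; the description
    field carries ``n_instances=K``.  Empty sets are skipped with a warning."""
    names = [s.drug_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names in GMT export")
    with open(path, "w") as fh:
        for s in sorted(sets, key=lambda s: s.drug_name):
            if not s.members:
                logger.warning("set %s has no members; skipped", s.drug_name)
                continue
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.drug_name}\tn_instances={s.n_instances}\t{members}\n")


def read_gmt(path: str | Path) -> list[DrugLncRNASet]:
    sets: list[DrugLncRNASet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            logger.warning("GMT %s line %d: set with no members; skipped", path, lineno)
            continue
        name, desc = parts[0], parts[1]
        if name in seen:
            raise ValueError(f"GMT {path} line {lineno}: duplicate set name {name!r}")
        seen.add(name)
        n_inst = 0
        if desc.startswith("n_instances="):
            n_inst = int(desc.split("=", 1)[1])
        members = frozenset(p for p in parts[2:] if p.strip())
        sets.append(
            DrugLncRNASet(drug_name=name, members=members, n_instances=n_inst)
        )
    return sets


# ---------------------------------------------------------------------------
# signature / result tables


def write_signatures(
    signatures: Sequence[InstanceSignature], path: str | Path
) -> None:
    """Long-format TSV: instance_id, gene_id, log2fc, del (up/down/empty)."""
    rows = []
    for sig in signatures:
        for gene_id in sorted(sig.log2fc.index):
            rows.append(
                {
                    "instance_id": sig.instance_id,
                    "gene_id": gene_id,
                    "log2fc": _fmt(sig.log2fc[gene_id]),
                    "del": sig.dels.get(gene_id, ""),
                }
            )
    pd.DataFrame(rows, columns=["instance_id", "gene_id", "log2fc", "del"]).to_csv(
        path, sep="\t", index=False
    )


def _write_table_with_header(
    frame: pd.DataFrame, path: str | Path, header_lines: Sequence[str]
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_ora_results(results, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    frame = pd.DataFrame(
        [
            {
                "drug": r.drug_name,
                "m": r.m,
                "t": r.t,
                "n": r.n,
                "r": r.r,
                "overlap_members": ",".join(sorted(r.overlap_members)),
                "p_value": _fmt(r.p_value),
                "q_value": _fmt(r.q_value),
            }
            for r in results
        ],
        columns=["drug", "m", "t", "n", "r", "overlap_members", "p_value", "q_value"],
    )
    _write_table_with_header(frame, path, header_lines)


def write_lsea_results(results, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    frame = pd.DataFrame(
        [
            {
                "drug": r.drug_name,
                "size": r.overlap_size,
                "es": _fmt(r.es),
                "nes": _fmt(r.nes) if r.nes_defined else "NA",
                "p_nominal": _fmt(r.p_nominal),
                "q_fdr": _fmt(r.q_fdr),
                "p_fwer": _fmt(r.p_fwer),
                "leading_edge": ",".join(sorted(r.leading_edge)),
            }
            for r in results
        ],
        columns=["drug", "size", "es", "nes", "p_nominal", "q_fdr", "p_fwer", "leading_edge"],
    )
    _write_table_with_header(frame, path, header_lines)
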