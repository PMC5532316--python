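"""Build per-instance lncRNA signatures and drug-induced lncRNA sets.

An *instance* is one perturbation experiment: a treatment array (cells
exposed to a small molecule) paired with one or more control arrays.  For
each instance we compute a gene-level log2 fold-change vector over the
reannotated lncRNA genes, call differentially expressed lncRNAs (DELs) at a
fold-change threshold, and finally merge DELs over all instances of the same
drug into that drug's *induced lncRNA set* — the unit against which query
lists and profiles are enriched.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
(or probe) row index, sample column index, and log2-scale intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reannotation import ReannotationMap

logger = logging.getLogger(__name__)


class Summarization(str, Enum):
    MEDIAN = "median"
    MEAN = "mean"


class DelDirection(str, Enum):
    BOTH = "both"
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class InstanceRecord:
    """One perturbation instance: treatment sample(s) vs control sample(s)."""

    instance_id: str
    drug_name: str
    treatment_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    platform: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.treatment_samples:
            raise ValueError(f"instance {self.instance_id!r}: no treatment samples")
        if not self.control_samples:
            raise ValueError(f"instance {self.instance_id!r}: no control samples")


@dataclass(frozen=True)
class SignatureParams:
    fc_threshold: float = 1.5
    summarization: Summarization = Summarization.MEDIAN
    del_direction: DelDirection = DelDirection.BOTH

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")

    @property
    def log2fc_cutoff(self) -> float:
        """Exact |log2 fold change| cutoff, e.g. log2(1.5) ~= 0.585."""
        return math.log2(self.fc_threshold)


@dataclass
class InstanceSignature:
    """Per-gene log2 fold changes for one instance, plus the called DELs."""

    instance_id: str
    log2fc: pd.Series  # index: gene_id
    dels: dict[str, str] = field(default_factory=dict)  # gene_id -> "up"/"down"

    @property
    def del_genes(self) -> set[str]:
        return set(self.dels)


@dataclass
class DrugLncRNASet:
    """Union of DELs over all instances of one drug."""

    drug_name: str
    members: frozenset[str]
    n_instances: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"drug set {self.drug_name!r} has no members")


def validate_expression_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in expression matrix: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in expression matrix: {dups[:5]}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def summarize_gene_expression(
    probe_matrix: pd.DataFrame,
    reannotation: ReannotationMap,
    method: Summarization = Summarization.MEDIAN,
) -> pd.DataFrame:
    """Summarize a probe-level matrix to the gene level.

    Each gene's value per sample is the median (default) or mean of its
    assigned probes' log2 intensities.  Probes listed in the reannotation map
    but absent from the matrix are skipped with a log message; a gene whose
    surviving probes fall below the map's ``min_probes_per_gene`` is dropped.
    """
    validate_expression_matrix(probe_matrix)
    method = Summarization(method)
    min_probes = reannotation.params.min_probes_per_gene

    rows: dict[str, np.ndarray] = {}
    present = set(probe_matrix.index)
    for gene_id, probe_ids in reannotation.gene_to_probes.items():
        avail = sorted(probe_ids & present)
        missing = len(probe_ids) - len(avail)
        if missing:
            logger.info(
                "gene %s: %d of %d probes absent from matrix",
                gene_id, missing, len(probe_ids),
            )
        if len(avail) == 0 or len(avail) < min_probes:
            logger.warning(
                "gene %s dropped: %d surviving probes < %d required",
                gene_id, len(avail), min_probes,
            )
            continue
        block = probe_matrix.loc[avail].to_numpy(dtype=float)
        if method is Summarization.MEDIAN:
            rows[gene_id] = np.median(block, axis=0)
        else:
            rows[gene_id] = block.mean(axis=0)

    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.columns)
    out = out.sort_index()
    out.index.name = "gene_id"
    return out


def instance_log2fc(expr: pd.DataFrame, inst: InstanceRecord) -> InstanceSignature:
    """Per-gene log2 fold change: mean over treatment minus mean over control.

    ``expr`` must already be gene-level and on the log2 scale, so the
    difference of sample means is the log2 fold change directly.
    """
    for sid in (*inst.treatment_samples, *inst.control_samples):
        if sid not in expr.columns:
            raise KeyError(
                f"instance {inst.instance_id!r} references sample {sid!r} "
                f"absent from the expression matrix"
            )
    treat = expr[list(inst.treatment_samples)].mean(axis=1)
    ctrl = expr[list(inst.control_samples)].mean(axis=1)
    lfc = (treat - ctrl).astype(float)
    lfc.name = inst.instance_id
    return InstanceSignature(instance_id=inst.instance_id, log2fc=lfc)


def call_dels(
    sig: InstanceSignature, params: SignatureParams
) -> InstanceSignature:
    """Call DELs: genes with |log2fc| >= log2(fc_threshold).

    The cutoff is the exact ``log2(fc_threshold)`` (about 0.585 at a 1.5-fold
    threshold), not a rounded display figure, so a gene at log2fc 0.58 is not
    a DEL at threshold 1.5.  Direction is the sign of the fold change;
    ``params.del_direction`` optionally restricts calls to one direction.
    """
    cutoff = params.log2fc_cutoff
    dels: dict[str, str] = {}
    for gene_id, lfc in sig.log2fc.items():
        if lfc >= cutoff and params.del_direction in (
            DelDirection.BOTH, DelDirection.UP
        ):
            dels[gene_id] = "up"
        elif lfc <= -cutoff and params.del_direction in (
            DelDirection.BOTH, DelDirection.DOWN
        ):
            dels[gene_id] = "down"
    sig.dels = dels
    return sig


def build_drug_sets(
    signatures: Sequence[InstanceSignature],
    instances: Sequence[InstanceRecord],
) -> list[DrugLncRNASet]:
    """Merge instance DELs into per-drug induced lncRNA sets.

    Members are the unsigned union of DELs over the drug's instances; a drug
    none of whose instances yields a DEL is omitted.  Output is sorted by
    drug name.
    """
    inst_by_id: dict[str, InstanceRecord] = {}
    for inst in instances:
        if inst.instance_id in inst_by_id:
            raise ValueError(f"duplicate instance_id {inst.instance_id!r}")
        inst_by_id[inst.instance_id] = inst

    per_drug_members: dict[str, set[str]] = {}
    per_drug_count: dict[str, int] = {}
    for sig in signatures:
        if sig.instance_id not in inst_by_id:
            raise KeyError(
                f"signature instance {sig.instance_id!r} missing from metadata"
            )
        drug = inst_by_id[sig.instance_id].drug_name
        per_drug_count[drug] = per_drug_count.get(drug, 0) + 1
        per_drug_members.setdefault(drug, set()).update(sig.del_genes)

    out = [
        DrugLncRNASet(
            drug_name=drug,
            members=frozenset(members),
            n_instances=per_drug_count[drug],
        )
        for drug, members in per_drug_members.items()
        if members
    ]
    out.sort(key=lambda s: s.drug_name)
    return out


def build_signatures(
    expr: pd.DataFrame,
    instances: Iterable[InstanceRecord],
    params: SignatureParams | None = None,
) -> list[InstanceSignature]:
    """Convenience composition: log2fc + DEL calling for every instance."""
    params = params or SignatureParams()
    validate_expression_matrix(expr)
    return [
        call_dels(instance_log2fc(expr, inst), params) for inst in instances
    ]
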