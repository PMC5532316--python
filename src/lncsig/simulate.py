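"""Seeded synthetic fixtures with known ground truth for every stage.

The generator emulates, at desk scale, the kind of data the pipeline is
built for: a mixed lncRNA / protein-coding transcriptome, 25-mer array
probes sampled from lncRNA transcripts (plus cross-biotype probes planted
into coding transcripts and decoy probes matching nothing), drug-perturbed
instance intensity matrices, and a two-class disease expression profile
whose shifted genes overlap one planted target drug's induced set.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so each artifact
(transcriptome, probes, intensities, disease profile) is independently
reproducible.  Intensities use a Gaussian log-intensity noise model: gene
baselines ~ Normal(7, 1) on the log2 scale, probe-level noise
~ Normal(0, noise_sd).  This is a transparency choice, not a claim of
fidelity to real microarray error structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reannotation import Biotype, ProbeRecord, TranscriptRecord
from .signatures import DrugLncRNASet, InstanceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_lnc_genes: int = 60
    n_coding_genes: int = 30
    transcripts_per_gene: tuple[int, int] = (1, 3)
    transcript_length: tuple[int, int] = (150, 400)
    probe_length: int = 25
    probes_per_gene: int = 8
    n_decoy_probes: int = 10
    cross_biotype_fraction: float = 0.1
    n_drugs: int = 8
    instances_per_drug: int = 3
    effect_genes_per_drug: int = 10
    effect_log2fc: float = 1.5
    noise_sd: float = 0.3
    n_disease_samples_per_class: int = 6
    target_drug_overlap: int = 8

    def __post_init__(self) -> None:
        for name in (
            "n_lnc_genes", "n_coding_genes", "probes_per_gene",
            "n_decoy_probes", "n_drugs", "instances_per_drug",
            "effect_genes_per_drug", "n_disease_samples_per_class",
            "target_drug_overlap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.cross_biotype_fraction <= 1:
            raise ValueError("cross_biotype_fraction must be in [0, 1]")
        if self.effect_log2fc < 0 or self.noise_sd < 0:
            raise ValueError("effect_log2fc and noise_sd must be >= 0")
        if self.transcript_length[0] < self.probe_length:
            raise ValueError("transcripts must be at least one probe long")

    def rngs(self, n: int = 4) -> list[np.random.Generator]:
        """Independent child generators: one per simulation stage."""
        return [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed).spawn(n)
        ]


@dataclass
class FixtureTruth:
    """Ground truth recorded at generation time, for end-to-end checks."""

    gene_to_probes: dict[str, set[str]] = field(default_factory=dict)
    #: probe_id -> "lnc_only" | "cross_biotype" | "decoy"
    probe_fate: dict[str, str] = field(default_factory=dict)
    #: drug -> {gene_id: "up" | "down"}
    drug_effects: dict[str, dict[str, str]] = field(default_factory=dict)
    disease_shifted_genes: list[str] = field(default_factory=list)
    target_drug: str = ""

    def expected_map(self, min_probes: int = 3) -> dict[str, set[str]]:
        """Gene -> probes expected to survive the full filter chain."""
        out: dict[str, set[str]] = {}
        for gene, probes in self.gene_to_probes.items():
            kept = {
                p for p in probes if self.probe_fate[p] == "lnc_only"
            }
            if len(kept) >= min_probes:
                out[gene] = kept
        return out

    def expected_del_sets(self) -> dict[str, set[str]]:
        return {d: set(eff) for d, eff in self.drug_effects.items() if eff}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_transcriptome(
    spec: FixtureSpec,
) -> list[TranscriptRecord]:
    """Random transcriptome: i.i.d. uniform nucleotide sequences.

    Gene ids are ``LNC####`` / ``PC####``; each gene gets a number of
    isoforms drawn uniformly from ``spec.transcripts_per_gene`` with lengths
    drawn from ``spec.transcript_length``.
    """
    if spec.n_lnc_genes + spec.n_coding_genes == 0:
        raise ValueError("at least one gene must be requested")
    rng = spec.rngs()[0]
    lo_t, hi_t = spec.transcripts_per_gene
    lo_l, hi_l = spec.transcript_length
    records: list[TranscriptRecord] = []
    for biotype, prefix, n_genes in (
        (Biotype.LNCRNA, "LNC", spec.n_lnc_genes),
        (Biotype.PROTEIN_CODING, "PC", spec.n_coding_genes),
    ):
        for g in range(n_genes):
            gene_id = f"{prefix}{g:04d}"
            n_iso = int(rng.integers(lo_t, hi_t + 1))
            for i in range(n_iso):
                length = int(rng.integers(lo_l, hi_l + 1))
                records.append(
                    TranscriptRecord(
                        transcript_id=f"{gene_id}.t{i + 1}",
                        gene_id=gene_id,
                        biotype=biotype,
                        sequence=_random_seq(rng, length),
                        gene_name=f"{prefix.lower()}-{g:04d}",
                    )
                )
    return records


def simulate_probes(
    transcripts: Sequence[TranscriptRecord],
    spec: FixtureSpec,
) -> tuple[list[ProbeRecord], list[TranscriptRecord], FixtureTruth]:
    """Sample probes from lncRNA transcripts; plant cross-biotype and decoys.

    Returns (probes, transcripts, truth).  The transcripts are returned
    because planting cross-biotype probes rewrites stretches of coding
    transcript sequence.  ``cross_biotype_fraction`` of all gene probes are
    copied into a coding transcript (at non-overlapping positions) so the
    cross-biotype filter must remove them; decoy probes are random sequences
    re-drawn until absent from every transcript on both strands.
    """
    from .reannotation import reverse_complement

    rng = spec.rngs()[1]
    plen = spec.probe_length
    txs = {t.transcript_id: t for t in transcripts}
    truth = FixtureTruth()
    probes: list[ProbeRecord] = []

    lnc_genes: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        if t.biotype is Biotype.LNCRNA:
            lnc_genes.setdefault(t.gene_id, []).append(t)

    for gene_id in sorted(lnc_genes):
        iso = lnc_genes[gene_id][0]
        n_pos = len(iso.sequence) - plen + 1
        if n_pos < spec.probes_per_gene:
            raise ValueError(
                f"gene {gene_id}: {n_pos} probe positions < "
                f"{spec.probes_per_gene} requested probes"
            )
        starts = rng.choice(n_pos, size=spec.probes_per_gene, replace=False)
        for k, start in enumerate(sorted(int(s) for s in starts)):
            pid = f"{gene_id}_p{k + 1}"
            probes.append(
                ProbeRecord(
                    probe_id=pid,
                    probeset_id=gene_id,
                    sequence=iso.sequence[start:start + plen],
                )
            )
            truth.gene_to_probes.setdefault(gene_id, set()).add(pid)
            truth.probe_fate[pid] = "lnc_only"

    # Plant cross-biotype probes into coding transcripts.
    coding = [t for t in transcripts if t.biotype is Biotype.PROTEIN_CODING]
    n_cross = int(round(spec.cross_biotype_fraction * len(probes)))
    if n_cross and not coding:
        raise ValueError("cross-biotype probes requested but no coding genes")
    if n_cross:
        used: dict[str, list[tuple[int, int]]] = {}
        chosen = rng.choice(len(probes), size=n_cross, replace=False)
        for idx in sorted(int(i) for i in chosen):
            probe = probes[idx]
            placed = False
            for _ in range(200):
                tx = coding[int(rng.integers(len(coding)))]
                pos = int(rng.integers(len(tx.sequence) - plen + 1))
                if any(
                    pos < e and pos + plen > s
                    for s, e in used.get(tx.transcript_id, [])
                ):
                    continue
                seq = tx.sequence
                new_seq = seq[:pos] + probe.sequence + seq[pos + plen:]
                txs[tx.transcript_id] = TranscriptRecord(
                    transcript_id=tx.transcript_id,
                    gene_id=tx.gene_id,
                    biotype=tx.biotype,
                    sequence=new_seq,
                    gene_name=tx.gene_name,
                )
                coding = [
                    txs[t.transcript_id] for t in coding
                ]
                used.setdefault(tx.transcript_id, []).append((pos, pos + plen))
                truth.probe_fate[probe.probe_id] = "cross_biotype"
                placed = True
                break
            if not placed:
                raise ValueError("could not place cross-biotype probe")

    # Verify fates against the emitted sequences: planting can make an
    # overlapping sibling probe match a coding transcript too, and (rarely)
    # a probe can collide with another lncRNA gene's sequence.
    lnc_by_gene: dict[str, list[str]] = {}
    coding_seqs = []
    for t in txs.values():
        if t.biotype is Biotype.LNCRNA:
            lnc_by_gene.setdefault(t.gene_id, []).append(t.sequence)
        else:
            coding_seqs.append(t.sequence)
    for probe in probes:
        seq = probe.sequence
        rc = reverse_complement(seq)
        if any(seq in s or rc in s for s in coding_seqs):
            truth.probe_fate[probe.probe_id] = "cross_biotype"
            continue
        own_gene = probe.probeset_id
        other = any(
            seq in s or rc in s
            for g, seqs in lnc_by_gene.items() if g != own_gene
            for s in seqs
        )
        if other:
            truth.probe_fate[probe.probe_id] = "multi_gene"

    # Decoys: random sequences absent from every transcript, both strands.
    all_seqs = [t.sequence for t in txs.values()]
    for d in range(spec.n_decoy_probes):
        for _ in range(200):
            seq = _random_seq(rng, plen)
            rc = reverse_complement(seq)
            if not any(seq in s or rc in s for s in all_seqs):
                pid = f"DECOY_p{d + 1}"
                probes.append(
                    ProbeRecord(probe_id=pid, probeset_id="DECOY", sequence=seq)
                )
                truth.probe_fate[pid] = "decoy"
                break
        else:
            raise ValueError("could not draw a decoy absent from transcriptome")

    out_transcripts = [txs[t.transcript_id] for t in transcripts]
    return probes, out_transcripts, truth


def simulate_instances(
    truth: FixtureTruth,
    spec: FixtureSpec,
    min_probes: int = 3,
) -> tuple[pd.DataFrame, list[InstanceRecord]]:
    """Probe-level intensity matrix plus instance metadata.

    Every drug shifts its effect genes by ``±effect_log2fc`` in the
    treatment sample of each of its instances (one treatment, two controls
    per instance).  Effect genes are drawn from the genes expected to
    survive reannotation, so noise-free runs recover the planted DEL sets
    exactly; the drawn effects are recorded in ``truth.drug_effects``.
    """
    rng = spec.rngs()[2]
    surviving = sorted(truth.expected_map(min_probes))
    if spec.effect_genes_per_drug > len(surviving):
        raise ValueError(
            f"effect_genes_per_drug={spec.effect_genes_per_drug} exceeds "
            f"{len(surviving)} available reannotated genes"
        )

    all_probes = sorted(truth.probe_fate)
    probe_gene = {
        p: g for g, ps in truth.gene_to_probes.items() for p in ps
    }
    baseline = {
        g: float(rng.normal(7.0, 1.0)) for g in sorted(truth.gene_to_probes)
    }
    decoy_baseline = {
        p: float(rng.normal(7.0, 1.0))
        for p in all_probes if p not in probe_gene
    }

    instances: list[InstanceRecord] = []
    columns: dict[str, np.ndarray] = {}
    truth.drug_effects = {}
    for d in range(spec.n_drugs):
        drug = f"drug{d + 1:03d}"
        eff_genes = rng.choice(
            surviving, size=spec.effect_genes_per_drug, replace=False
        )
        signs = rng.choice([1.0, -1.0], size=spec.effect_genes_per_drug)
        effect = {
            str(g): float(s) * spec.effect_log2fc
            for g, s in zip(eff_genes, signs)
        }
        truth.drug_effects[drug] = {
            g: ("up" if v > 0 else "down") for g, v in effect.items()
        } if spec.effect_log2fc > 0 else {}
        for i in range(spec.instances_per_drug):
            inst_id = f"{drug}_i{i + 1}"
            treat = f"{inst_id}_T1"
            ctrls = (f"{inst_id}_C1", f"{inst_id}_C2")
            instances.append(
                InstanceRecord(
                    instance_id=inst_id,
                    drug_name=drug,
                    treatment_samples=(treat,),
                    control_samples=ctrls,
                )
            )
            for sample in (treat, *ctrls):
                vals = np.empty(len(all_probes))
                for j, p in enumerate(all_probes):
                    g = probe_gene.get(p)
                    v = baseline[g] if g else decoy_baseline[p]
                    if sample == treat and g in effect:
                        v += effect[g]
                    vals[j] = v
                if spec.noise_sd > 0:
                    vals = vals + rng.normal(0, spec.noise_sd, len(all_probes))
                columns[sample] = vals

    matrix = pd.DataFrame(columns, index=all_probes)
    matrix.index.name = "probe_id"
    return matrix, instances


def simulate_disease_profile(
    drug_sets: Sequence[DrugLncRNASet],
    universe: Sequence[str],
    spec: FixtureSpec,
    target_drug: str | None = None,
    truth: FixtureTruth | None = None,
) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """Two-class gene-level profile with a planted best-matching drug.

    Class-1 (disease) samples shift ``target_drug_overlap`` members of the
    target drug's set upward by ``effect_log2fc`` over Gaussian noise.
    Returns the expression matrix (for LSEA), the 0/1 sample labels, and
    the shifted-gene list (the ORA query).
    """
    if spec.n_disease_samples_per_class < 1:
        raise ValueError("need at least one sample per class")
    rng = spec.rngs()[3]
    by_name = {ds.drug_name: ds for ds in drug_sets}
    if target_drug is None:
        target_drug = sorted(by_name)[0] if by_name else ""
    if target_drug not in by_name:
        raise ValueError(f"target drug {target_drug!r} absent from drug sets")

    universe = sorted(set(universe))
    members = sorted(set(by_name[target_drug].members) & set(universe))
    if not members:
        raise ValueError(
            f"target drug {target_drug!r} has no members in the universe"
        )
    k = min(spec.target_drug_overlap, len(members))
    shifted = sorted(
        str(g) for g in rng.choice(members, size=k, replace=False)
    )

    n = spec.n_disease_samples_per_class
    samples0 = [f"N{i + 1}" for i in range(n)]
    samples1 = [f"D{i + 1}" for i in range(n)]
    baseline = rng.normal(7.0, 1.0, len(universe))
    shift = np.array(
        [spec.effect_log2fc if g in set(shifted) else 0.0 for g in universe]
    )
    data = {}
    for s in samples0:
        data[s] = baseline + rng.normal(0, spec.noise_sd, len(universe))
    for s in samples1:
        data[s] = baseline + shift + rng.normal(0, spec.noise_sd, len(universe))
    expr = pd.DataFrame(data, index=universe)
    expr.index.name = "gene_id"
    labels = {**{s: 0 for s in samples0}, **{s: 1 for s in samples1}}

    if truth is not None:
        truth.disease_shifted_genes = list(shifted)
        truth.target_drug = target_drug
    return expr, labels, list(shifted)
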