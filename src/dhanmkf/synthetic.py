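"""Planted-block synthetic fixtures.

The generator emulates a curated circRNA-drug sensitivity dataset at desk
scale: circRNAs and drugs are assigned to latent co-modules; associations
are Bernoulli(p_in) within a module and Bernoulli(p_out) outside; host-gene
sequences descend from per-module ancestor sequences (so within-module
Levenshtein similarity exceeds between-module similarity) and drug
fingerprints descend from per-module ancestor bit sets (same property under
Tanimoto).  Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import AssociationMatrix, EntityIndex, write_association_matrix

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    n_circ: int = 60
    n_drug: int = 40
    n_blocks: int = 3
    p_in: float = 0.5
    p_out: float = 0.05
    seq_len: int = 200
    mut_in: float = 0.05
    mut_out: float = 0.4
    fp_bits: int = 512
    fp_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not self.mut_in < self.mut_out:
            raise ValueError("require mut_in < mut_out")


@dataclass
class SyntheticDataset:
    matrix: AssociationMatrix
    sequences: dict[str, str]
    fingerprints: dict[str, np.ndarray]
    circ_blocks: np.ndarray
    drug_blocks: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)


def _blocks(rng: np.random.Generator, n: int, n_blocks: int) -> np.ndarray:
    """Random block assignment, resampled until no block is empty."""
    for _ in range(100):
        labels = rng.integers(0, n_blocks, size=n)
        if len(np.unique(labels)) == n_blocks:
            return labels
    raise RuntimeError("could not populate all blocks")


def _mutate_seq(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = rng.random(len(seq)) < rate
    # substitute with a uniformly random *other* base
    shifts = rng.integers(1, 4, size=int(hits.sum()))
    idx = np.nonzero(hits)[0]
    base_idx = np.searchsorted(BASES, out[idx])
    out[idx] = BASES[(base_idx + shifts) % 4]
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one fixture: association matrix + sequences + fingerprints."""
    rng = np.random.default_rng(spec.seed)
    circ_blocks = _blocks(rng, spec.n_circ, spec.n_blocks)
    drug_blocks = _blocks(rng, spec.n_drug, spec.n_blocks)

    same = circ_blocks[:, None] == drug_blocks[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)
    values = (rng.random((spec.n_circ, spec.n_drug)) < probs).astype(np.int8)

    circ_ids = tuple(f"circ{i:03d}" for i in range(spec.n_circ))
    drug_ids = tuple(f"drug{j:03d}" for j in range(spec.n_drug))
    matrix = AssociationMatrix(
        values,
        EntityIndex(circ_ids, "circRNA"),
        EntityIndex(drug_ids, "drug"),
    )

    # sequences: global ancestor -> per-block ancestors (mut_out)
    #            -> members (mut_in)
    root = rng.choice(BASES, size=spec.seq_len)
    block_seqs = [_mutate_seq(rng, root, spec.mut_out) for _ in range(spec.n_blocks)]
    sequences = {
        cid: "".join(_mutate_seq(rng, block_seqs[b], spec.mut_in))
        for cid, b in zip(circ_ids, circ_blocks)
    }

    # fingerprints: same two-level mutation scheme on bit sets
    root_fp = (rng.random(spec.fp_bits) < spec.fp_density).astype(np.uint8)
    block_fps = [
        np.where(rng.random(spec.fp_bits) < spec.mut_out, 1 - root_fp, root_fp)
        for _ in range(spec.n_blocks)
    ]
    fingerprints = {
        did: np.where(
            rng.random(spec.fp_bits) < spec.mut_in, 1 - block_fps[b], block_fps[b]
        ).astype(np.uint8)
        for did, b in zip(drug_ids, drug_blocks)
    }

    return SyntheticDataset(
        matrix=matrix,
        sequences=sequences,
        fingerprints=fingerprints,
        circ_blocks=circ_blocks,
        drug_blocks=drug_blocks,
        spec=spec,
    )


def degree_profile(matrix: AssociationMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree histograms (circRNA side, drug side); bin k counts nodes of degree k."""
    values = matrix.values if isinstance(matrix, AssociationMatrix) else np.asarray(matrix)
    deg_c = values.sum(axis=1).astype(int)
    deg_d = values.sum(axis=0).astype(int)
    return np.bincount(deg_c), np.bincount(deg_d)


def similarity_inputs(data: SyntheticDataset) -> tuple[np.ndarray, np.ndarray]:
    """CSS/DSS of a fixture via the similarity module."""
    from .similarity import sequence_similarity_matrix, structure_similarity_matrix

    css = sequence_similarity_matrix(data.sequences, data.matrix.row_index)
    dss = structure_similarity_matrix(data.fingerprints, data.matrix.col_index)
    return css, dss


def write_fixture(data: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the formats the io layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "sequences": outdir / "sequences.fasta",
        "fingerprints": outdir / "fingerprints.tsv",
        "blocks": outdir / "blocks.tsv",
    }
    write_association_matrix(data.matrix, paths["associations"])
    with open(paths["sequences"], "w") as fh:
        for cid, seq in data.sequences.items():
            fh.write(f">{cid}\n{seq}\n")
    with open(paths["fingerprints"], "w") as fh:
        fh.write("id\tbits\n")
        for did, fp in data.fingerprints.items():
            fh.write(f"{did}\t{''.join(map(str, fp.tolist()))}\n")
    with open(paths["blocks"], "w") as fh:
        fh.write("id\tblock\n")
        for cid, b in zip(data.matrix.row_index.ids, data.circ_blocks.tolist()):
            fh.write(f"{cid}\t{b}\n")
        for did, b in zip(data.matrix.col_index.ids, data.drug_blocks.tolist()):
            fh.write(f"{did}\t{b}\n")
    return paths
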