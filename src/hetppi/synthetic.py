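"""Synthetic heterogeneous networks with planted, recoverable signal.

Proteins are partitioned into communities; PPIs are drawn Bernoulli with a
higher rate inside communities than across them (a planted-partition
model), non-protein molecules (lncRNA, miRNA, disease, drug) each attach to
the proteins of one random community, and every community carries a private
amino-acid motif injected into its members' otherwise-uniform sequences.
Both views — network neighbourhood and sequence composition — therefore
carry label-relevant community signal, at independently tunable strengths.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .hetnet import HeteroNetwork, NodeRef, TypedEdge, write_edge_table
from .inter_view import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: relation used to attach each non-protein node type to proteins
_CROSS_RELATION = {
    "lncRNA": "lncRNA-protein",
    "miRNA": "miRNA-protein",
    "disease": "protein-disease",
    "drug": "drug-protein",
}
_TYPE_PREFIX = {"protein": "P", "lncRNA": "L", "miRNA": "MI", "disease": "DI", "drug": "DR"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are the fixed study conditions used by the
    acceptance checks (see :func:`default_acceptance_config`)."""

    n_proteins: int = 300
    n_lncRNA: int = 100
    n_miRNA: int = 100
    n_disease: int = 100
    n_drug: int = 100
    n_communities: int = 6
    p_ppi_within: float = 0.15
    p_ppi_between: float = 0.005
    p_cross_type: float = 0.05
    motif_length: int = 6
    motif_injection_rate: float = 0.8
    sequence_length_range: tuple[int, int] = (80, 300)
    seed: int = 1213

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not 1 <= self.n_communities <= self.n_proteins:
            raise ValueError("n_communities must be in [1, n_proteins]")
        for name in ("p_ppi_within", "p_ppi_between", "p_cross_type", "motif_injection_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo, hi = self.sequence_length_range
        if lo < self.motif_length or hi < lo:
            raise ValueError("sequence_length_range must be ordered and >= motif_length")


def default_acceptance_config() -> SyntheticConfig:
    """The fixed configuration the acceptance checks run on: 300 proteins in
    6 communities (p_within=0.15, p_between=0.005), 100 nodes of each other
    type attached at rate 0.05, length-6 motifs injected at rate 0.8 into
    sequences of 80-300 residues, seed 1213."""
    return SyntheticConfig()


def generate(
    cfg: SyntheticConfig,
) -> tuple[HeteroNetwork, list[SequenceRecord], dict]:
    """Sample one dataset: the typed network, the protein sequences and a
    manifest recording the planted communities and motifs."""
    rng = np.random.default_rng(cfg.seed)
    n, n_comm = cfg.n_proteins, cfg.n_communities
    community = np.array([i * n_comm // n for i in range(n)])
    proteins = [NodeRef(f"P{i:04d}", "protein") for i in range(n)]

    net = HeteroNetwork(nodes=proteins)

    # planted-partition PPI layer
    iu, jv = np.triu_indices(n, k=1)
    same = community[iu] == community[jv]
    p = np.where(same, cfg.p_ppi_within, cfg.p_ppi_between)
    hit = rng.random(len(p)) < p
    for i, j in zip(iu[hit], jv[hit]):
        net.add_edge(TypedEdge(proteins[int(i)], proteins[int(j)], "protein-protein"))

    # cross-type attachments: each non-protein node adopts one community
    for ntype, count in (
        ("lncRNA", cfg.n_lncRNA),
        ("miRNA", cfg.n_miRNA),
        ("disease", cfg.n_disease),
        ("drug", cfg.n_drug),
    ):
        relation = _CROSS_RELATION[ntype]
        for idx in range(count):
            node = NodeRef(f"{_TYPE_PREFIX[ntype]}{idx:04d}", ntype)
            net.add_node(node)
            home = int(rng.integers(n_comm))
            members = np.flatnonzero(community == home)
            attach = members[rng.random(len(members)) < cfg.p_cross_type]
            for m in attach:
                net.add_edge(TypedEdge(node, proteins[int(m)], relation))

    # community motifs, guaranteed pairwise distinct
    motifs: list[str] = []
    while len(motifs) < n_comm:
        candidate = "".join(rng.choice(list(AMINO_ACIDS), size=cfg.motif_length))
        if candidate not in motifs:
            motifs.append(candidate)

    lo, hi = cfg.sequence_length_range
    records: list[SequenceRecord] = []
    for i, prot in enumerate(proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list(AMINO_ACIDS), size=length)
        if rng.random() < cfg.motif_injection_rate:
            motif = motifs[community[i]]
            pos = int(rng.integers(0, length - cfg.motif_length + 1))
            seq[pos : pos + cfg.motif_length] = list(motif)
        records.append(SequenceRecord(prot.id, "".join(seq)))

    manifest = {
        "config": asdict(cfg),
        "communities": {
            str(c): [proteins[int(i)].id for i in np.flatnonzero(community == c)]
            for c in range(n_comm)
        },
        "motifs": {str(c): motifs[c] for c in range(n_comm)},
    }
    return net, records, manifest


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


def write_dataset(
    net: HeteroNetwork, records: list[SequenceRecord], outdir: str | Path
) -> dict[str, Path]:
    """Write the generated data through the standard formats so downstream
    stages exercise the real readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "edges": write_edge_table(net, outdir / "edges.tsv"),
        "fasta": write_fasta(records, outdir / "sequences.fasta"),
    }
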