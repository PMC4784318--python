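"""File formats, configuration, and the synthetic fixture generator.

Tables are TSV with header rows.  A gate-fraction table ships as two
files: the main table (``variant_id`` plus columns ``t_1..t_m``) and a
gate sidecar (``gate``, ``lower``, ``upper``, ``T``).  Read-count tables
are analogous (``r_1..r_m`` plus optional ``seq``; sidecar column ``h``
holds per-gate sorted-cell totals).  Sequences travel as FASTA
(Biopython); run configuration as YAML.  Column layouts are documented in
FORMATS.md at the repository root.

The fixture generator fabricates gate-fraction and read-count tables in
the style of published 32-gate sort-seq exports, together with the hidden
per-variant ground truth, so every downstream routine can be exercised
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distributions import GateConfig, gate_probabilities, moments_to_params
from .estimate import GateFractionTable, QCThresholds
from .regroup import ReadCountTable
from .seqmodel import SequenceVariant


# ---------------------------------------------------------------------------
# gate sidecar


def write_gates(path, gates: GateConfig, totals: np.ndarray | None = None,
                totals_name: str = "T") -> None:
    frame = gates.to_frame()
    if totals is not None:
        frame[totals_name] = np.asarray(totals)
    frame.to_csv(path, sep="\t", index=False)


def read_gates(path, totals_name: str = "T") -> tuple[GateConfig, np.ndarray | None]:
    frame = pd.read_csv(path, sep="\t")
    gates = GateConfig.from_frame(frame)
    totals = frame[totals_name].to_numpy(float) if totals_name in frame else None
    return gates, totals


# ---------------------------------------------------------------------------
# gate-fraction tables


def write_gate_fraction_table(table_path, gates_path, table: GateFractionTable) -> None:
    frame = table.fractions.copy()
    frame.columns = [f"t_{j + 1}" for j in range(table.gates.m)]
    frame.index.name = "variant_id"
    frame.to_csv(table_path, sep="\t")
    write_gates(gates_path, table.gates, table.T, "T")


def read_gate_fraction_table(
    table_path, gates_path, tol: float = 1e-6
) -> GateFractionTable:
    """Load and validate a gate-fraction table.

    Rows whose fractions do not sum to 1 (beyond ``tol``) are rejected
    with an error naming the offending lines.
    """
    gates, T = read_gates(gates_path)
    if T is None:
        raise ValueError(f"{gates_path}: missing per-gate totals column 'T'")
    frame = pd.read_csv(table_path, sep="\t", index_col="variant_id")
    cols = [f"t_{j + 1}" for j in range(gates.m)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{table_path}: missing fraction columns {missing}")
    frame = frame[cols]
    sums = frame.to_numpy(float).sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"{table_path}: fractions do not sum to 1 on line(s) {lines}"
        )
    return GateFractionTable(fractions=frame, gates=gates, T=T)


# ---------------------------------------------------------------------------
# read-count tables


def write_read_count_table(table_path, gates_path, table: ReadCountTable) -> None:
    frame = table.counts.copy()
    frame.columns = [f"r_{j + 1}" for j in range(table.gates.m)]
    if table.sequences is not None:
        frame.insert(0, "seq", table.sequences)
    frame.index.name = "variant_id"
    frame.to_csv(table_path, sep="\t")
    write_gates(gates_path, table.gates, table.h, "h")


def read_read_count_table(table_path, gates_path) -> ReadCountTable:
    gates, h = read_gates(gates_path, "h")
    if h is None:
        raise ValueError(f"{gates_path}: missing per-gate totals column 'h'")
    frame = pd.read_csv(table_path, sep="\t", index_col="variant_id")
    sequences = frame.pop("seq") if "seq" in frame.columns else None
    cols = [f"r_{j + 1}" for j in range(gates.m)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{table_path}: missing count columns {missing}")
    return ReadCountTable(counts=frame[cols], gates=gates, h=h, sequences=sequences)


# ---------------------------------------------------------------------------
# sequences and models


def write_fasta(path, variants) -> None:
    records = [
        SeqRecord(Seq(v.bases), id=v.id or f"variant_{i}", description="")
        for i, v in enumerate(variants)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[SequenceVariant]:
    return [
        SequenceVariant(bases=str(rec.seq).upper(), id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_activity_model(path, model, interactions_path=None) -> None:
    """Write the additive table (position, base, H) and, when present and a
    path is given, the pairwise table (p1, q1, p2, q2, J)."""
    h_frame, j_frame = model.to_frames()
    with open(path, "w") as fh:
        fh.write(f"# reference\t{model.reference}\n")
        fh.write(f"# G0\t{model.G0}\n")
        h_frame.to_csv(fh, sep="\t", index=False)
    if j_frame is not None and interactions_path is not None:
        j_frame.to_csv(interactions_path, sep="\t", index=False)


def read_activity_model(path, interactions_path=None):
    """Read a model written by :func:`write_activity_model`."""
    from .seqmodel import ALPHABET, ActivityModel

    import io as _io

    lines = Path(path).read_text().splitlines(keepends=True)
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition("\t")
        header[key.strip()] = value
    frame = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    reference = header["reference"]
    G0 = float(header["G0"])
    P = len(reference)
    H = np.zeros((P, 4))
    for _, row in frame.iterrows():
        H[int(row["position"]) - 1, ALPHABET.index(row["base"])] = row["H"]
    J = None
    if interactions_path is not None:
        j_frame = pd.read_csv(interactions_path, sep="\t")
        J = np.zeros((P, 4, P, 4))
        for _, row in j_frame.iterrows():
            p1, q1 = int(row["p1"]) - 1, ALPHABET.index(row["q1"])
            p2, q2 = int(row["p2"]) - 1, ALPHABET.index(row["q2"])
            J[p1, q1, p2, q2] = J[p2, q2, p1, q1] = row["J"]
    return ActivityModel(reference=reference, G0=G0, H=H, J=J)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    qc: QCThresholds = QCThresholds()
    gamma: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCThresholds(**raw.get("qc", {}))
        return cls(seed=int(raw.get("seed", 0)), qc=qc,
                   gamma=float(raw.get("gamma", 0.05)))

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "gamma": self.gamma,
            "qc": {
                "reads_min": self.qc.reads_min,
                "single_gate_max": self.qc.single_gate_max,
                "two_gate_max": self.qc.two_gate_max,
                "censor_max": self.qc.censor_max,
                "dkl_max_bits": self.qc.dkl_max_bits,
            },
        }
        Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_fixture_library(
    n_variants: int,
    nu_range: tuple[float, float],
    sigma_range: tuple[float, float],
    gates: GateConfig,
    reads_per_variant: int,
    rng: np.random.Generator,
) -> tuple[GateFractionTable, pd.DataFrame]:
    """Fabricate a gate-fraction table plus its hidden ground truth.

    Per variant, nu is drawn log-uniformly over ``nu_range`` and sigma
    uniformly over ``sigma_range``; gate fractions are multinomial samples
    of ``reads_per_variant`` reads from the analytic gate probabilities
    (renormalised over the gates, i.e. conditioned on being sorted).
    Returns the observable table and a truth frame with columns
    nu, sigma, mu, n_reads.
    """
    lo, hi = nu_range
    if not (0 < lo < hi):
        raise ValueError("need 0 < nu_range[0] < nu_range[1]")
    s_lo, s_hi = sigma_range
    if not (0 < s_lo <= s_hi):
        raise ValueError("need 0 < sigma_range[0] <= sigma_range[1]")
    nus = np.exp(rng.uniform(math.log(lo), math.log(hi), n_variants))
    sigmas = rng.uniform(s_lo, s_hi, n_variants)
    rows, truth = [], []
    for i, (nu, sigma) in enumerate(zip(nus, sigmas)):
        c = math.sqrt(math.expm1(sigma * sigma))
        mu, _ = moments_to_params(nu, c)
        p = gate_probabilities(gates, mu, sigma)
        p = p / p.sum()
        counts = rng.multinomial(reads_per_variant, p)
        rows.append(counts / reads_per_variant)
        truth.append({"nu": nu, "sigma": sigma, "mu": mu, "n_reads": reads_per_variant})
    ids = [f"v{i:05d}" for i in range(n_variants)]
    fractions = pd.DataFrame(
        np.asarray(rows), index=pd.Index(ids, name="variant_id"),
        columns=[f"t_{j + 1}" for j in range(gates.m)],
    )
    T = fractions.to_numpy().sum(axis=0)
    T = T / T.sum()
    table = GateFractionTable(fractions=fractions, gates=gates, T=T)
    return table, pd.DataFrame(truth, index=fractions.index)
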