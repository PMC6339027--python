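"""Multi-party privacy-preserving decision-tree training.

Actors
------
* **Trusted Authority (TA)** — setup only: generates one Paillier pair shared
  by all hospitals and the cloud's RSA pair, and distributes them.  The cloud
  receives the Paillier *public* key only; it can aggregate ciphertexts but
  never decrypt them.
* **Hospitals** — hold the records.  Each round, every hospital counts the
  (attribute value × class) frequency matrix of the current partition for
  every attribute still available, adds its secret session nonce ``z`` to
  every cell, Paillier-encrypts cell by cell, and sends the matrices plus the
  RSA-sealed nonce to the cloud.  The nonce stops a curious co-holder of the
  shared Paillier key from reading an intercepted matrix.
* **Cloud** — opens each hospital's sealed nonce, removes the blinding
  homomorphically (multiplies each cell by ``g^{−z}``), sums corresponding
  cells across hospitals, and broadcasts the encrypted pooled matrices.

Hospitals decrypt the pooled matrices, compute information gain, and all
arrive at the same split decision; the cloud is told only the chosen
attribute.  Child partitions are resolved from the rows of the chosen
attribute's pooled matrix (a row *is* the child's class-count vector):
empty rows and pure rows close as leaves immediately, the rest are queued
and processed depth-first in schema-value order.  Because every decision is
a deterministic function of the pooled counts, every hospital grows the
identical tree — which must equal the single-site reference tree on the
pooled records.

Records never leave a hospital; the protocol's messages carry only
ciphertexts, sealed nonces, and the split/leaf decisions themselves.  What
the design knowingly reveals to participants: the pooled aggregate
frequencies and the pooled dataset size.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from random import Random
from typing import Dict, List, Optional, Sequence, Tuple, Union
import warnings

import numpy as np

from . import paillier
from .paillier import (
    PaillierCiphertext,
    PaillierPrivateKey,
    PaillierPublicKey,
    h_add,
    h_add_const,
)
from . import envelope as _env
from .envelope import RsaKeyPair, RsaPublicKey, SealedNonce, open_nonce, seal_nonce
from .dataset import (
    AttributeSchema,
    ClinicalDataset,
    FrequencyMatrix,
    SplitPath,
    count_frequencies,
)
from .c45 import DecisionNode, DecisionTree, majority_class, select_split

__all__ = [
    "ProtocolError",
    "BlindingOverflowError",
    "ConsensusError",
    "TrustedAuthority",
    "HospitalActor",
    "CloudActor",
    "EncryptedMatrix",
    "RoundDecision",
    "TrainingSession",
    "ta_setup",
    "hospital_prepare_round",
    "cloud_aggregate",
    "hospital_finalize_round",
    "run_training",
    "complexity",
]


class ProtocolError(Exception):
    """Protocol-level inconsistency (mismatched submissions, bad state)."""


class BlindingOverflowError(ProtocolError):
    """count + z would wrap modulo the Paillier modulus; use a larger key or smaller nonce."""


class ConsensusError(ProtocolError):
    """Hospitals disagreed on a round decision — must be impossible; correctness tripwire."""


@dataclass
class EncryptedMatrix:
    """A frequency matrix with every cell Paillier-encrypted (blinded or pooled)."""

    attribute: str
    values: Tuple[str, ...]
    classes: Tuple[str, ...]
    cells: List[List[PaillierCiphertext]]
    hospital_id: str = ""

    @property
    def shape(self) -> Tuple[int, int]:
        return (len(self.values), len(self.classes))


@dataclass
class TrustedAuthority:
    """Setup-time key generator/distributor; idle during training rounds."""

    paillier_pk: PaillierPublicKey
    paillier_sk: PaillierPrivateKey
    cloud_rsa: RsaKeyPair
    distribution_log: List[str] = field(default_factory=list)


@dataclass
class HospitalActor:
    id: str
    dataset: ClinicalDataset
    paillier_pk: PaillierPublicKey
    paillier_sk: PaillierPrivateKey
    cloud_rsa_pk: RsaPublicKey
    nonce: int
    rng: Random
    tree: Optional[DecisionTree] = None


@dataclass
class CloudActor:
    """Holds its RSA pair and the Paillier public key only — it cannot decrypt counts."""

    rsa: RsaKeyPair
    paillier_pk: PaillierPublicKey


ChildOutcome = Tuple[str, Union[Tuple[str, str], str]]  # (value, ("leaf", label) | "open")


@dataclass(frozen=True)
class RoundDecision:
    """The consensus outcome of one round at one partition.

    Either a leaf (``kind == "leaf"``) or a split: the chosen attribute, the
    partition's majority class (the fallback label for empty descendants),
    and the per-child outcome derived from the pooled matrix rows.
    """

    kind: str  # "leaf" | "split"
    label: Optional[str] = None
    attribute: Optional[str] = None
    majority: Optional[str] = None
    children: Tuple[ChildOutcome, ...] = ()


@dataclass
class TrainingSession:
    """Round state: the open-partition queue, decision log, and message capture."""

    schema: AttributeSchema
    seed: Optional[int] = None
    round: int = 0
    decisions: List[Tuple[SplitPath, RoundDecision]] = field(default_factory=list)
    message_log: List[dict] = field(default_factory=list)

    def send(self, message: dict) -> None:
        self.message_log.append(message)


# --------------------------------------------------------------------------
# setup


def ta_setup(
    datasets: Sequence[ClinicalDataset],
    paillier_bits: int = 2048,
    rsa_bits: int = 2048,
    nonce_bits: int = 32,
    seed: Optional[int] = None,
) -> Tuple[List[HospitalActor], CloudActor, TrainingSession]:
    """TA key generation and distribution for one training session.

    Every hospital receives the same Paillier pair and the cloud's RSA public
    key, plus a private uniformly drawn session nonce; the cloud receives its
    RSA pair and the Paillier public key only.
    """
    if not datasets:
        raise ProtocolError("at least one hospital dataset is required")
    if not 1 <= nonce_bits <= 32:
        raise ProtocolError("nonce_bits must lie in [1, 32]")
    schema = datasets[0].schema
    for d in datasets[1:]:
        if d.schema != schema:
            raise ProtocolError("all hospitals must share one attribute schema")
    master = Random(seed) if seed is not None else Random()
    pk, sk = paillier.generate_keypair(paillier_bits, seed=master.randrange(1 << 30))
    rsa = _env.rsa_generate(rsa_bits, seed=master.randrange(1 << 30))
    total = sum(len(d) for d in datasets)
    if total + (1 << nonce_bits) >= pk.n:
        raise BlindingOverflowError("Paillier modulus too small for the nonce range")
    ta = TrustedAuthority(paillier_pk=pk, paillier_sk=sk, cloud_rsa=rsa)
    cloud = CloudActor(rsa=rsa, paillier_pk=pk)
    hospitals = []
    for i, d in enumerate(datasets):
        hrng = Random(master.randrange(1 << 30))
        z = hrng.randrange(1, 1 << nonce_bits)
        hospitals.append(
            HospitalActor(
                id=f"H{i + 1}",
                dataset=d,
                paillier_pk=pk,
                paillier_sk=sk,
                cloud_rsa_pk=rsa.public,
                nonce=z,
                rng=hrng,
            )
        )
        ta.distribution_log.append(f"H{i + 1}: paillier pair + cloud RSA public key")
    ta.distribution_log.append("cloud: RSA pair + paillier public key")
    session = TrainingSession(schema=schema, seed=seed)
    return hospitals, cloud, session


# --------------------------------------------------------------------------
# one round, actor by actor


def hospital_prepare_round(
    h: HospitalActor, path: SplitPath, available_attrs: Sequence[str]
) -> Tuple[List[EncryptedMatrix], SealedNonce]:
    """Count, blind with the session nonce, and encrypt — one matrix per attribute."""
    if not available_attrs:
        raise ProtocolError("no attributes available to count")
    out = []
    n = h.paillier_pk.n
    for attr in available_attrs:
        m = count_frequencies(h.dataset, attr, path)
        rows = []
        for row in m.cells:
            enc_row = []
            for count in row:
                blinded = int(count) + h.nonce
                if blinded >= n:
                    raise BlindingOverflowError(
                        f"count {count} + nonce exceeds the Paillier modulus"
                    )
                enc_row.append(paillier.encrypt(h.paillier_pk, blinded, rng=h.rng))
            rows.append(enc_row)
        out.append(
            EncryptedMatrix(
                attribute=attr,
                values=m.values,
                classes=m.classes,
                cells=rows,
                hospital_id=h.id,
            )
        )
    sealed = seal_nonce(h.cloud_rsa_pk, h.nonce, hospital_id=h.id, rng=h.rng)
    return out, sealed


def cloud_aggregate(
    cloud: CloudActor,
    submissions: Sequence[Tuple[List[EncryptedMatrix], SealedNonce]],
) -> List[EncryptedMatrix]:
    """Secure attribute-frequency addition at the cloud.

    For each hospital the sealed nonce is opened with the cloud's RSA private
    key and subtracted from every cell in the plaintext space by multiplying
    the ciphertext with ``g^{−z}``; the unblinded ciphertexts are then summed
    cell-wise across hospitals.  No Paillier decryption happens here — the
    cloud holds no Paillier private key.
    """
    if not submissions:
        raise ProtocolError("no submissions to aggregate")
    ref = submissions[0][0]
    sig = [(m.attribute, m.shape) for m in ref]
    for mats, _ in submissions[1:]:
        if [(m.attribute, m.shape) for m in mats] != sig:
            raise ProtocolError("hospitals submitted mismatched attributes or dimensions")
    pk = cloud.paillier_pk
    pooled: List[EncryptedMatrix] = []
    unblinded: List[List[List[List[PaillierCiphertext]]]] = []
    for mats, sealed in submissions:
        z = open_nonce(cloud.rsa, sealed)
        unblinded.append(
            [
                [[h_add_const(pk, c, -z) for c in row] for row in m.cells]
                for m in mats
            ]
        )
    for mi, m in enumerate(ref):
        k, l = m.shape
        rows = []
        for a in range(k):
            row = []
            for b in range(l):
                acc = unblinded[0][mi][a][b]
                for hosp in unblinded[1:]:
                    acc = h_add(pk, acc, hosp[mi][a][b])
                row.append(acc)
            rows.append(row)
        pooled.append(
            EncryptedMatrix(
                attribute=m.attribute, values=m.values, classes=m.classes, cells=rows
            )
        )
    return pooled


def hospital_finalize_round(
    h: HospitalActor,
    pooled: Sequence[EncryptedMatrix],
    remaining_attrs: Sequence[str],
    fallback: Optional[str] = None,
) -> RoundDecision:
    """Decrypt the pooled matrices and decide: close as a leaf or pick the split.

    The decision is a deterministic function of the pooled counts, so every
    hospital computes the same :class:`RoundDecision` independently.  For a
    split, each child value's outcome is read off the chosen matrix's rows:
    an empty row closes with the partition's majority class, a pure row with
    its class, a depth-exhausted row with its own majority; anything else
    stays open for the next round.
    """
    matrices: Dict[str, FrequencyMatrix] = {}
    for em in pooled:
        cells = np.array(
            [[paillier.decrypt(h.paillier_sk, c) for c in row] for row in em.cells],
            dtype=np.int64,
        )
        matrices[em.attribute] = FrequencyMatrix(
            attribute=em.attribute, values=em.values, classes=em.classes, cells=cells
        )
    labels = h.dataset.schema.class_labels
    first = matrices[pooled[0].attribute]
    class_totals = first.column_sums
    total = int(class_totals.sum())
    if total == 0:
        return RoundDecision(kind="leaf", label=fallback)
    nonzero = np.flatnonzero(class_totals)
    if len(nonzero) == 1:
        return RoundDecision(kind="leaf", label=labels[int(nonzero[0])])
    maj = majority_class(class_totals, labels)
    split = select_split({a: matrices[a] for a in (m.attribute for m in pooled)})
    sm = matrices[split]
    depth_exhausted = len(remaining_attrs) == 1  # only the split attribute was left
    children: List[ChildOutcome] = []
    for j, value in enumerate(sm.values):
        row = sm.cells[j]
        rs = int(row.sum())
        if rs == 0:
            children.append((value, ("leaf", maj)))
        elif len(np.flatnonzero(row)) == 1:
            children.append((value, ("leaf", labels[int(np.argmax(row))])))
        elif depth_exhausted:
            children.append((value, ("leaf", majority_class(row, labels))))
        else:
            children.append((value, "open"))
    return RoundDecision(
        kind="split", attribute=split, majority=maj, children=tuple(children)
    )


# --------------------------------------------------------------------------
# orchestration


def _hex_cells(em: EncryptedMatrix) -> List[List[str]]:
    return [[f"{c.value:x}" for c in row] for row in em.cells]


def _decision_payload(d: RoundDecision) -> dict:
    if d.kind == "leaf":
        return {"kind": "leaf", "label": d.label}
    return {
        "kind": "split",
        "attribute": d.attribute,
        "children": [[v, list(o) if o != "open" else "open"] for v, o in d.children],
    }


def run_training(
    hospitals: Sequence[HospitalActor],
    cloud: CloudActor,
    session: TrainingSession,
) -> DecisionTree:
    """Run the full recursive protocol; every hospital ends with the same tree.

    Partitions are processed depth-first, child values in schema order.  Any
    cross-hospital disagreement aborts with :class:`ConsensusError` naming
    the round and partition.
    """
    if sum(len(h.dataset) for h in hospitals) == 0:
        raise ProtocolError("the pooled dataset is empty")
    schema = session.schema

    def process(path: SplitPath, fallback: Optional[str]) -> DecisionNode:
        session.round += 1
        rnd = session.round
        avail = [a for a in schema.attribute_names if a not in path.attributes]
        session.send(
            {"type": "prompt", "round": rnd, "partition_path": list(path.constraints)}
        )
        submissions = []
        for h in hospitals:
            mats, sealed = hospital_prepare_round(h, path, avail)
            for em in mats:
                session.send(
                    {
                        "type": "submission",
                        "round": rnd,
                        "hospital_id": h.id,
                        "partition_path": list(path.constraints),
                        "attribute": em.attribute,
                        "cells": _hex_cells(em),
                        "sealed_nonce": base64.b64encode(sealed.ciphertext).decode(),
                    }
                )
            submissions.append((mats, sealed))
        pooled = cloud_aggregate(cloud, submissions)
        for em in pooled:
            session.send(
                {
                    "type": "aggregate",
                    "round": rnd,
                    "attribute": em.attribute,
                    "cells": _hex_cells(em),
                }
            )
        decisions = [
            hospital_finalize_round(h, pooled, avail, fallback) for h in hospitals
        ]
        for h, d in zip(hospitals, decisions):
            session.send(
                {
                    "type": "decision",
                    "round": rnd,
                    "hospital_id": h.id,
                    **_decision_payload(d),
                }
            )
        if any(d != decisions[0] for d in decisions[1:]):
            raise ConsensusError(
                f"hospitals disagreed in round {rnd} at partition {path.constraints}"
            )
        decision = decisions[0]
        session.decisions.append((path, decision))
        if decision.kind == "leaf":
            return DecisionNode(class_label=decision.label)
        children: Dict[str, DecisionNode] = {}
        for value, outcome in decision.children:
            if outcome == "open":
                children[value] = process(
                    path.extend(decision.attribute, value), decision.majority
                )
            else:
                children[value] = DecisionNode(class_label=outcome[1])
        return DecisionNode(attribute=decision.attribute, children=children)

    root = process(SplitPath(), None)
    tree = DecisionTree(
        root=root,
        schema=schema,
        metadata={"algorithm": "ppsdt", "rounds": session.round},
    )
    for h in hospitals:
        h.tree = DecisionTree(root=root, schema=schema, metadata=dict(tree.metadata))
    return tree


def complexity(schema: AttributeSchema) -> int:
    """Matrix-cell workload per hospital per round: attributes × classes × values.

    Assumes a uniform attribute-value count; with ragged domains the maximum
    domain size is used and a warning emitted.
    """
    sizes = {len(v) for v in schema.value_domains.values()}
    if len(sizes) > 1:
        warnings.warn("non-uniform value domains: using the maximum domain size")
    return len(schema.attribute_names) * len(schema.class_labels) * max(sizes)
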