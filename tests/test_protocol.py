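"""Tests for the multi-party training protocol: setup, rounds, privacy, orchestration."""

import base64
import json
from random import Random

import numpy as np
import pandas as pd
import pytest

from ppsdt import paillier, protocol
from ppsdt.c45 import build_tree_plaintext, information_gain
from ppsdt.dataset import (
    AttributeSchema,
    ClinicalDataset,
    FrequencyMatrix,
    SplitPath,
    count_frequencies,
    default_schema,
    generate_synthetic,
    nausea_fixture,
)
from ppsdt.protocol import (
    BlindingOverflowError,
    EncryptedMatrix,
    ProtocolError,
    cloud_aggregate,
    complexity,
    hospital_finalize_round,
    hospital_prepare_round,
    run_training,
    ta_setup,
)
from conftest import pooled


def setup_federation(n_hospitals=3, per_hospital=10, seed=7, noise=0.0):
    sets = generate_synthetic(n_hospitals, per_hospital, noise_rate=noise, seed=seed)
    hospitals, cloud, session = ta_setup(sets, paillier_bits=512, rsa_bits=512, seed=seed)
    return sets, hospitals, cloud, session


class TestSetup:
    def test_shared_paillier_distinct_nonces(self):
        _, hospitals, cloud, _ = setup_federation(3)
        assert len(hospitals) == 3
        assert len({h.paillier_pk.n for h in hospitals}) == 1
        assert len({h.paillier_sk.lam for h in hospitals}) == 1
        assert len({h.nonce for h in hospitals}) == 3
        assert cloud.paillier_pk.n == hospitals[0].paillier_pk.n

    def test_cloud_never_holds_paillier_secret(self):
        _, _, cloud, _ = setup_federation(2)
        # neither λ nor μ appear anywhere in the cloud's state
        assert not hasattr(cloud, "paillier_sk")
        assert "lam" not in repr(cloud.paillier_pk) and "mu" not in repr(cloud.paillier_pk)

    def test_seeded_setup_reproducible(self):
        sets = generate_synthetic(2, 5, seed=1)
        h1, _, _ = ta_setup(sets, paillier_bits=256, rsa_bits=512, seed=11)
        h2, _, _ = ta_setup(sets, paillier_bits=256, rsa_bits=512, seed=11)
        assert h1[0].paillier_pk.n == h2[0].paillier_pk.n
        assert [h.nonce for h in h1] == [h.nonce for h in h2]

    def test_mismatched_schemas_rejected(self):
        a = generate_synthetic(1, 5, seed=1)[0]
        other = AttributeSchema(("Q",), {"Q": ("0", "1")}, ("x", "y"))
        b = ClinicalDataset(schema=other, frame=pd.DataFrame({"Q": ["0"], "class": ["x"]}))
        with pytest.raises(ProtocolError):
            ta_setup([a, b], paillier_bits=256, rsa_bits=512, seed=1)

    def test_nonce_range_vs_modulus_checked(self):
        sets = generate_synthetic(1, 5, seed=1)
        with pytest.raises(BlindingOverflowError):
            ta_setup(sets, paillier_bits=32, rsa_bits=512, nonce_bits=32, seed=1)


class TestPrepareRound:
    def test_cells_decrypt_to_blinded_counts_only(self):
        sets, hospitals, _, _ = setup_federation(2, per_hospital=8)
        h = hospitals[0]
        mats, _ = hospital_prepare_round(h, SplitPath(), ["N", "UP"])
        assert [m.attribute for m in mats] == ["N", "UP"]
        for em in mats:
            plain = count_frequencies(h.dataset, em.attribute)
            for a in range(len(em.values)):
                for b in range(len(em.classes)):
                    got = paillier.decrypt(h.paillier_sk, em.cells[a][b])
                    assert got == int(plain.cells[a, b]) + h.nonce
                    assert got != int(plain.cells[a, b])  # nonce ≥ 1: never the bare count

    def test_empty_partition_encrypts_pure_nonce(self):
        sets, hospitals, _, _ = setup_federation(1, per_hospital=4)
        h = hospitals[0]
        # a path no record satisfies: constrain every attribute to the values of no record
        path = SplitPath((("N", "0"), ("LP", "0"), ("UP", "0"), ("MP", "0")))
        empty_path = path if len(
            h.dataset.frame.query("N=='0' and LP=='0' and UP=='0' and MP=='0'")
        ) == 0 else SplitPath((("N", "1"), ("LP", "1"), ("UP", "1"), ("MP", "1")))
        mats, _ = hospital_prepare_round(h, empty_path, ["BU"])
        sub = count_frequencies(h.dataset, "BU", empty_path)
        if sub.total == 0:
            for row in mats[0].cells:
                for c in row:
                    assert paillier.decrypt(h.paillier_sk, c) == h.nonce

    def test_no_attributes_rejected(self):
        _, hospitals, _, _ = setup_federation(1)
        with pytest.raises(ProtocolError):
            hospital_prepare_round(hospitals[0], SplitPath(), [])


class TestCloudAggregate:
    def test_single_hospital_identity(self):
        sets, hospitals, cloud, _ = setup_federation(1, per_hospital=6)
        h = hospitals[0]
        sub = hospital_prepare_round(h, SplitPath(), ["N"])
        pooled_mats = cloud_aggregate(cloud, [sub])
        plain = count_frequencies(h.dataset, "N")
        got = [
            [paillier.decrypt(h.paillier_sk, c) for c in row] for row in pooled_mats[0].cells
        ]
        assert got == plain.cells.tolist()

    def test_three_hospitals_elementwise_sum(self):
        sets, hospitals, cloud, _ = setup_federation(3, per_hospital=7)
        subs = [hospital_prepare_round(h, SplitPath(), ["N", "MP"]) for h in hospitals]
        pooled_mats = cloud_aggregate(cloud, subs)
        for em in pooled_mats:
            expected = sum(
                count_frequencies(h.dataset, em.attribute).cells for h in hospitals
            )
            got = [
                [paillier.decrypt(hospitals[0].paillier_sk, c) for c in row]
                for row in em.cells
            ]
            assert got == expected.tolist()

    def test_worked_example_aggregate_from_synthetic_split(self, test_key, rsa_key):
        # three synthetic per-hospital matrices summing to the published aggregate
        fixture, _ = nausea_fixture()
        parts = [
            np.array([[3, 1, 2, 0], [0, 1, 0, 2]]),
            np.array([[3, 1, 2, 0], [0, 1, 0, 1]]),
            np.array([[2, 1, 1, 0], [0, 0, 0, 1]]),
        ]
        assert sum(parts).tolist() == fixture.cells.tolist()
        pk, sk = test_key
        cloud = protocol.CloudActor(rsa=rsa_key, paillier_pk=pk)
        rng = Random(4)
        subs = []
        from ppsdt.envelope import seal_nonce

        for i, cells in enumerate(parts):
            z = rng.randrange(1, 1 << 32)
            em = EncryptedMatrix(
                attribute="N",
                values=("0", "1"),
                classes=("0", "1", "2", "3"),
                cells=[
                    [paillier.encrypt(pk, int(v) + z, rng=rng) for v in row]
                    for row in cells
                ],
                hospital_id=f"H{i}",
            )
            subs.append(([em], seal_nonce(rsa_key.public, z, rng=rng)))
        out = cloud_aggregate(cloud, subs)
        got = [[paillier.decrypt(sk, c) for c in row] for row in out[0].cells]
        assert got == [[8, 3, 5, 0], [0, 2, 0, 4]]

    def test_mismatched_submissions_rejected(self):
        _, hospitals, cloud, _ = setup_federation(2)
        s1 = hospital_prepare_round(hospitals[0], SplitPath(), ["N"])
        s2 = hospital_prepare_round(hospitals[1], SplitPath(), ["LP"])
        with pytest.raises(ProtocolError):
            cloud_aggregate(cloud, [s1, s2])

    def test_cloud_code_path_never_decrypts(self, monkeypatch):
        _, hospitals, cloud, _ = setup_federation(2, per_hospital=5)
        subs = [hospital_prepare_round(h, SplitPath(), ["N", "BU"]) for h in hospitals]

        def forbidden(*a, **k):
            raise AssertionError("cloud invoked Paillier decryption")

        monkeypatch.setattr(paillier, "decrypt", forbidden)
        cloud_aggregate(cloud, subs)  # must complete without decrypting


class TestFinalizeRound:
    def _pooled_round(self, hospitals, cloud, attrs, path=SplitPath()):
        subs = [hospital_prepare_round(h, path, attrs) for h in hospitals]
        return cloud_aggregate(cloud, subs)

    def test_pure_aggregate_becomes_leaf(self, test_key, rsa_key):
        pk, sk = test_key
        h = protocol.HospitalActor(
            id="H1",
            dataset=generate_synthetic(1, 3, seed=1)[0],
            paillier_pk=pk,
            paillier_sk=sk,
            cloud_rsa_pk=rsa_key.public,
            nonce=5,
            rng=Random(0),
        )
        cells = [[paillier.encrypt(pk, v) for v in row] for row in [[0, 6, 0, 0], [0, 3, 0, 0]]]
        em = EncryptedMatrix(attribute="N", values=("0", "1"), classes=("0", "1", "2", "3"), cells=cells)
        d = hospital_finalize_round(h, [em], ["N"])
        assert d.kind == "leaf" and d.label == "1"

    def test_worked_example_split_decision(self, test_key, rsa_key):
        pk, sk = test_key
        fixture, _ = nausea_fixture()
        h = protocol.HospitalActor(
            id="H1",
            dataset=generate_synthetic(1, 3, seed=1)[0],
            paillier_pk=pk,
            paillier_sk=sk,
            cloud_rsa_pk=rsa_key.public,
            nonce=5,
            rng=Random(0),
        )
        cells = [[paillier.encrypt(pk, int(v)) for v in row] for row in fixture.cells]
        em = EncryptedMatrix(attribute="N", values=fixture.values, classes=fixture.classes, cells=cells)
        d = hospital_finalize_round(h, [em], ["N", "LP"])
        assert d.kind == "split" and d.attribute == "N"
        assert information_gain(fixture) == pytest.approx(0.6247, abs=1e-3)

    def test_all_hospitals_reach_identical_decisions(self):
        for seed in range(10):
            sets, hospitals, cloud, _ = setup_federation(3, per_hospital=6, seed=seed, noise=0.2)
            pooled_mats = self._pooled_round(hospitals, cloud, list(default_schema().attribute_names))
            decisions = [
                hospital_finalize_round(h, pooled_mats, default_schema().attribute_names)
                for h in hospitals
            ]
            assert all(d == decisions[0] for d in decisions)


class TestRunTraining:
    def test_single_hospital_equals_plaintext_oracle(self):
        sets, hospitals, cloud, session = setup_federation(1, per_hospital=20, seed=3)
        tree = run_training(hospitals, cloud, session)
        assert tree == build_tree_plaintext(sets[0])
        assert hospitals[0].tree == tree

    def test_three_hospitals_equal_pooled_oracle(self):
        sets, hospitals, cloud, session = setup_federation(3, per_hospital=20, seed=9, noise=0.1)
        tree = run_training(hospitals, cloud, session)
        assert tree == build_tree_plaintext(pooled(sets))
        assert all(h.tree == tree for h in hospitals)

    def test_partition_invariance_with_determining_attribute(self):
        base = generate_synthetic(1, 24, seed=5)[0]
        frame = base.frame.copy()
        frame["class"] = frame["MP"].map({"0": "0", "1": "2"})
        full = ClinicalDataset(schema=base.schema, frame=frame)
        ref = None
        for cut in (1, 8, 12):
            parts = [
                ClinicalDataset(schema=base.schema, frame=frame.iloc[:cut]),
                ClinicalDataset(schema=base.schema, frame=frame.iloc[cut:]),
            ]
            hs, cloud, session = ta_setup(parts, paillier_bits=512, rsa_bits=512, seed=2)
            tree = run_training(hs, cloud, session)
            assert tree.root.attribute == "MP"
            assert all(c.is_leaf for c in tree.root.children.values())
            ref = ref or tree
            assert tree == ref == build_tree_plaintext(full)

    def test_master_seed_reproducibility(self):
        runs = []
        for _ in range(2):
            sets, hospitals, cloud, session = setup_federation(2, per_hospital=10, seed=31)
            run_training(hospitals, cloud, session)
            runs.append(session.message_log)
        assert runs[0] == runs[1]

    def test_empty_union_rejected(self, toy_dataset):
        empty = ClinicalDataset(schema=toy_dataset.schema, frame=toy_dataset.frame.iloc[:0])
        hs, cloud, session = ta_setup([empty], paillier_bits=256, rsa_bits=512, seed=1)
        with pytest.raises(ProtocolError):
            run_training(hs, cloud, session)


@pytest.fixture(scope="module")
def traffic():
    sets, hospitals, cloud, session = setup_federation(3, per_hospital=8, seed=19)
    run_training(hospitals, cloud, session)
    return sets, hospitals, session.message_log


class TestPrivacyContracts:

    def test_no_raw_records_or_counts_in_messages(self, traffic):
        sets, hospitals, log = traffic
        text = json.dumps(log)
        # dataset rows never serialized: message vocabulary is fixed
        allowed = {
            "type", "round", "partition_path", "hospital_id", "attribute",
            "cells", "sealed_nonce", "kind", "label", "children",
        }
        for msg in log:
            assert set(msg) <= allowed
        # every transmitted cell is a Paillier ciphertext, far above any raw count
        for msg in log:
            if msg["type"] == "submission":
                for row in msg["cells"]:
                    for hexval in row:
                        assert int(hexval, 16) > 10**60

    def test_no_plaintext_nonce_in_traffic(self, traffic):
        _, hospitals, log = traffic
        for h in hospitals:
            for msg in log:
                sealed = msg.get("sealed_nonce", "")
                assert str(h.nonce) not in json.dumps(
                    {k: v for k, v in msg.items() if k != "cells"}
                )
                if sealed:
                    assert h.nonce.to_bytes(8, "big") not in base64.b64decode(sealed)

    def test_intercepted_matrices_decrypt_only_to_blinded_values(self, traffic):
        sets, hospitals, log = traffic
        sk = hospitals[0].paillier_sk
        by_id = {h.id: h for h in hospitals}
        pk = hospitals[0].paillier_pk
        for msg in log:
            if msg["type"] != "submission":
                continue
            h = by_id[msg["hospital_id"]]
            path = SplitPath(tuple((a, v) for a, v in msg["partition_path"]))
            plain = count_frequencies(h.dataset, msg["attribute"], path)
            for a, row in enumerate(msg["cells"]):
                for b, hexval in enumerate(row):
                    ct = paillier.PaillierCiphertext(value=int(hexval, 16), key_id=pk.key_id)
                    assert paillier.decrypt(sk, ct) == int(plain.cells[a, b]) + h.nonce


class TestComplexity:
    def test_reference_schema_workload(self):
        assert complexity(default_schema()) == 5 * 4 * 2 == 40

    def test_degenerate_schema(self):
        s = AttributeSchema(("A",), {"A": ("v",)}, ("c",))
        assert complexity(s) == 1

    def test_matches_cells_prepared_per_round(self):
        sets, hospitals, cloud, _ = setup_federation(1, per_hospital=5)
        attrs = list(default_schema().attribute_names)
        mats, _ = hospital_prepare_round(hospitals[0], SplitPath(), attrs)
        n_cells = sum(len(m.values) * len(m.classes) for m in mats)
        assert n_cells == complexity(default_schema())

    def test_non_uniform_domains_warn(self):
        s = AttributeSchema(
            ("A", "B"), {"A": ("0", "1"), "B": ("0", "1", "2")}, ("x", "y")
        )
        with pytest.warns(UserWarning):
            assert complexity(s) == 2 * 2 * 3
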