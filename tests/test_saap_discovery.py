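import dataclasses

import numpy as np
import pytest

from glycorbf import saap_discovery, sequence_io, synthetic
from glycorbf.features import fscore
from glycorbf.saap_discovery import (
    SAAP,
    enumerate_pairs,
    rank_and_select,
    select_anchor,
)
from glycorbf.sequence_io import NEGATIVE, POSITIVE, SiteFragment


def frag(window, label, pid="P", pos=50):
    n = (len(window) - 1) // 2
    return SiteFragment(pid, pos, window[n], window, label)


def indicator_fscore(fragments, saap):
    """Direct evaluation of the pair's 0/1 indicator feature."""
    n = fragments[0].n
    vals = {POSITIVE: [], NEGATIVE: []}
    for f in fragments:
        hit = float(
            f.window[saap.anchor_pos + n] == saap.anchor_res
            and f.window[saap.partner_pos + n] in saap.partner_set
        )
        vals[f.label].append(hit)
    return fscore(vals[POSITIVE], vals[NEGATIVE])


@pytest.fixture(scope="module")
def implanted_fragments(implanted_dataset):
    return implanted_dataset[2]


class TestSelectAnchor:
    def test_implanted_anchor_recovered(self):
        cfg = synthetic.SimConfig(
            n_proteins=30,
            length_range=(60, 150),
            fraction_tm=0.0,
            implanted_saaps=(synthetic.ImplantSpec(3, "T", None, (), 0.9),),
            n_positive_sites=40,
            n_negative_sites=400,
            seed=123,
        )
        records, sites, _ = synthetic.generate(cfg)
        frags = sequence_io.build_fragments(records, sites, 14)
        anchor = select_anchor(frags)
        assert anchor.position == 3
        assert anchor.residues[0] == "T"

    def test_no_signal_anchor_still_in_valid_range(self, implanted_fragments):
        rng = np.random.default_rng(9)
        labels = np.array([f.label for f in implanted_fragments])
        rng.shuffle(labels)
        perm = [dataclasses.replace(f, label=l)
                for f, l in zip(implanted_fragments, labels)]
        anchor = select_anchor(perm)
        assert -14 <= anchor.position <= 14 and anchor.position != 0

    def test_single_informative_position_selected(self):
        # constant alphabet except one position that separates the classes
        pos = [frag("APSAA", POSITIVE, pid=f"A{i}") for i in range(3)]
        neg = [frag("AGSAA", NEGATIVE, pid=f"B{i}") for i in range(3)]
        assert select_anchor(pos + neg).position == -1

    def test_k_anchor_truncates_residue_list(self, implanted_fragments):
        assert len(select_anchor(implanted_fragments, k_anchor=2).residues) <= 2


class TestEnumeratePairs:
    def test_stored_fscores_match_direct_recomputation(self, implanted_fragments):
        anchor = select_anchor(implanted_fragments)
        for saap in enumerate_pairs(implanted_fragments, anchor)[:40]:
            assert saap.fscore == pytest.approx(
                indicator_fscore(implanted_fragments, saap), abs=1e-12, rel=1e-12
            )

    def test_implanted_pair_outranks_all_others(self, implanted_fragments):
        anchor = select_anchor(implanted_fragments)
        ranked = enumerate_pairs(implanted_fragments, anchor)
        top = ranked[0]
        implanted_positions = {top.anchor_pos, top.partner_pos}
        assert implanted_positions == {3, 9}
        assert {top.anchor_res} | set(top.partner_set) <= {"T", "E"}

    def test_merged_partner_set_beats_both_singletons(self):
        # positives carry anchor P at -1 and either E or D at +2; negatives
        # carry the anchor with an unrelated partner, so the {D, E} merge wins
        pos = []
        for i in range(10):
            partner = "E" if i % 2 else "D"
            pos.append(frag("APSA" + partner, POSITIVE, pid=f"A{i}"))
        neg = [frag("APSAG", NEGATIVE, pid=f"B{i}") for i in range(10)]
        neg += [frag("AGSAW", NEGATIVE, pid=f"C{i}") for i in range(10)]
        anchor = select_anchor(pos + neg)
        ranked = enumerate_pairs(pos + neg, anchor, f_min=0.10)
        merged = [s for s in ranked if len(s.partner_set) == 2]
        assert merged, "a two-residue partner set should have been emitted"
        best = merged[0]
        assert set(best.partner_set) == {"D", "E"}
        for res in best.partner_set:
            single = next(
                s
                for s in ranked
                if s.partner_set == (res,)
                and s.partner_pos == best.partner_pos
                and s.anchor_res == best.anchor_res
            )
            assert best.fscore > single.fscore

    def test_partner_sets_capped_at_two_residues(self, implanted_fragments):
        anchor = select_anchor(implanted_fragments)
        assert all(
            len(s.partner_set) <= 2
            for s in enumerate_pairs(implanted_fragments, anchor)
        )


class TestRankAndSelect:
    def test_perfectly_separating_pair_gives_prefix_one(self):
        separator = SAAP(3, "T", 9, ("E",), 5.0)
        noise = [SAAP(-5, "A", 2, ("G",), 0.5), SAAP(1, "C", -2, ("W",), 0.2)]

        def trainer(fragments, prefix):
            # CV stand-in: the separating pair alone maximizes performance
            return 1.0 if separator in prefix else 0.5

        result = rank_and_select([separator] + noise, [], trainer, max_pairs=10)
        assert result.selected == [separator]
        assert result.curve[0] == (0, 0.5)

    def test_uninformative_candidates_give_empty_prefix(self):
        noise = [SAAP(-5, "A", 2, ("G",), 0.5), SAAP(1, "C", -2, ("W",), 0.2)]

        def trainer(fragments, prefix):
            return 0.7 - 0.01 * len(prefix)

        result = rank_and_select(noise, [], trainer, max_pairs=10)
        assert result.selected == []

    def test_tie_prefers_shorter_prefix(self):
        pairs = [SAAP(1, "A", 2, ("G",), 1.0), SAAP(1, "C", 2, ("G",), 0.9)]
        result = rank_and_select(pairs, [], lambda f, p: 0.8, max_pairs=5)
        assert result.selected == []

    def test_bad_max_pairs_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select([], [], lambda f, p: 0.5, max_pairs=0)

    def test_selection_deterministic(self, implanted_dataset):
        records, sites, fragments, sequences = implanted_dataset
        from glycorbf.pipeline_eval import make_cv_trainer

        anchor = select_anchor(fragments)
        candidates = enumerate_pairs(fragments, anchor)[:3]
        trainer = make_cv_trainer(sequences, seed=5, homology="none")
        first = rank_and_select(candidates, fragments, trainer, max_pairs=3)
        second = rank_and_select(candidates, fragments, trainer, max_pairs=3)
        assert first.selected == second.selected
        assert first.curve == second.curve


def test_saap_table_round_trip(tmp_path):
    saaps = [SAAP(3, "T", 9, ("E", "T"), 0.071), SAAP(-7, "T", 2, ("S",), 0.064)]
    path = tmp_path / "saaps.tsv"
    saap_discovery.write_saap_table(saaps, "S", "TM", path)
    rows = saap_discovery.read_saap_table(path)
    assert [(c, k) for c, k, _ in rows] == [("S", "TM"), ("S", "TM")]
    assert [s for _, _, s in rows] == saaps
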