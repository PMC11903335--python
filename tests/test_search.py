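"""Pair mode, database search, clustered expansion, TSV reporting, CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from multimeralign import (
    align_pair,
    make_complex_pair,
    make_decoy_pair,
    parse_results,
    random_fixture_spec,
    search_clustered,
    search_database,
    write_pdb,
    write_results,
)
from multimeralign.fixtures import FixtureSpec
from multimeralign.search import _length_gate, main, read_cluster_map
from multimeralign.structures import ComplexStructure


def _noisy_variant(base_spec, variant_seed, sigma=0.3, name=None):
    """A structure equivalent to the base fixture's query up to a rigid motion
    plus noise: reuse the same spec but with a different global motion."""
    spec = FixtureSpec(
        base_spec.n_chains,
        base_spec.chain_lengths,
        base_spec.inter_chain_transforms,
        sigma,
        base_spec.chain_permutation,
        base_spec.seed,
    )
    q, t, _, _ = make_complex_pair(spec)
    rng = np.random.default_rng(variant_seed)
    from multimeralign.fixtures import random_rigid_transform
    from multimeralign.structures import ChainStructure

    g = random_rigid_transform(rng)
    chains = [
        ChainStructure(
            c.chain_id,
            g.apply(c.ca_coords) + rng.normal(0, sigma, c.ca_coords.shape),
            list(c.residue_names),
            list(c.residue_numbers),
        )
        for c in q.chains
    ]
    return ComplexStructure(name or f"v{variant_seed}", chains)


def test_homodimer_pair_alignment():
    spec = random_fixture_spec(301, n_chains=2, noise_sigma=0.3)
    q, t, _, _ = make_complex_pair(spec)
    aln = align_pair(q, t)
    assert len(aln.chain_pairs) == 2
    assert max(aln.tm_query_norm, aln.tm_target_norm) >= 0.9


def test_unrelated_decoy_scores_below_cutoff():
    """Same chains, independently re-placed: complex TM falls below the 0.65
    similarity cutoff even though every chain matches individually."""
    below = 0
    for k in range(5):
        spec = random_fixture_spec(400 + k, n_chains=3, noise_sigma=0.5)
        q, decoy, _ = make_decoy_pair(spec)
        aln = align_pair(q, decoy)
        matched_spec_aln = align_pair(q, make_complex_pair(spec)[1])
        assert aln.tm_query_norm < matched_spec_aln.tm_query_norm
        if max(aln.tm_query_norm, aln.tm_target_norm) < 0.65:
            below += 1
    assert below >= 4


def test_monomer_vs_monomer_degenerates_to_chain_alignment():
    spec = random_fixture_spec(305, n_chains=1, noise_sigma=0.2)
    q, t, _, _ = make_complex_pair(spec)
    aln = align_pair(q, t)
    assert len(aln.chain_pairs) == 1
    chain_aln = aln.per_pair_alignments[0]
    assert aln.tm_query_norm == pytest.approx(
        chain_aln.tm_query_norm * len(q.chains[0]) / q.total_length, abs=1e-6
    )


def test_search_ranks_true_target_first():
    spec = random_fixture_spec(310, n_chains=2, noise_sigma=0.0)
    q, _, _, _ = make_complex_pair(spec)
    true_target = ComplexStructure("truth", q.chains)
    decoys = []
    for k in range(4):
        dq, _, _ = make_decoy_pair(random_fixture_spec(320 + k, n_chains=2, noise_sigma=0.0))
        decoys.append(ComplexStructure(f"decoy{k}", dq.chains))
    results = search_database([q], decoys + [true_target], threshold=0.0)
    assert results[0].target_id == "truth"
    assert results[0].tm_query_norm == pytest.approx(1.0, abs=1e-6)


def test_search_empty_targets():
    spec = random_fixture_spec(311, n_chains=2, noise_sigma=0.0)
    q, _, _, _ = make_complex_pair(spec)
    assert search_database([q], []) == []


def test_monomer_targets_rejected_for_multimer_queries():
    dimer_spec = random_fixture_spec(312, n_chains=2, noise_sigma=0.0)
    q, _, _, _ = make_complex_pair(dimer_spec)
    mono = ComplexStructure("mono", [q.chains[0]])
    assert search_database([q], [mono], threshold=0.0) == []
    hits = search_database([q], [mono], threshold=0.0, include_monomers=True)
    assert [h.target_id for h in hits] == ["mono"]


def test_prescreen_gate_is_conservative():
    """The length gate may only skip pairs where every chain-length ratio
    exceeds 3x, which cannot carry a TM >= 0.65 hit."""
    for k in range(20):
        spec = random_fixture_spec(500 + k, noise_sigma=0.5)
        q, t, _, _ = make_complex_pair(spec)
        assert not _length_gate(q, t)  # genuine pairs always pass the gate
    spec = random_fixture_spec(550, n_chains=2, noise_sigma=0.0, length_range=(30, 31))
    q_small, _, _, _ = make_complex_pair(spec)
    spec_big = random_fixture_spec(551, n_chains=2, noise_sigma=0.0, length_range=(100, 110))
    q_big, _, _, _ = make_complex_pair(spec_big)
    assert _length_gate(q_small, q_big)


def test_clustered_search_expansion_finds_planted_member():
    base = random_fixture_spec(600, n_chains=2, noise_sigma=0.0)
    rep = _noisy_variant(base, 601, sigma=0.4, name="rep0")
    member = _noisy_variant(base, 602, sigma=0.2, name="mem0")
    query = _noisy_variant(base, 603, sigma=0.2, name="q0")
    unrelated, _, _ = make_decoy_pair(random_fixture_spec(610, n_chains=2, noise_sigma=0.0))
    unrelated = ComplexStructure("rep1", unrelated.chains)
    cluster_map = {"rep0": ["rep0", "mem0"], "rep1": ["rep1"]}
    members = {"rep0": rep, "mem0": member, "rep1": unrelated}
    results = search_clustered(
        [query], [rep, unrelated], cluster_map, members,
        expand_threshold=0.3, threshold=0.65,
    )
    assert "mem0" in {r.target_id for r in results}
    # with no representative passing, results shrink to representative hits
    strict = search_clustered(
        [query], [rep, unrelated], cluster_map, members,
        expand_threshold=1.01, threshold=0.65,
    )
    assert {r.target_id for r in strict} <= {"rep0", "rep1"}


def test_write_parse_roundtrip(tmp_path):
    spec = random_fixture_spec(700, n_chains=2, noise_sigma=0.2)
    q, t, _, _ = make_complex_pair(spec)
    aln = align_pair(q, t)
    out = tmp_path / "hits.tsv"
    write_results([aln], out)
    text = out.read_text().splitlines()
    assert text[0].startswith("#query_id\t")
    rows = parse_results(out)
    assert len(rows) == 1
    row = rows[0]
    assert row["query_id"] == aln.query_id and row["target_id"] == aln.target_id
    assert row["qtm"] == pytest.approx(aln.tm_query_norm, abs=5e-5)
    np.testing.assert_allclose(row["rotation"], aln.transform.rotation, atol=5e-7)
    np.testing.assert_allclose(row["translation"], aln.transform.translation, atol=5e-4)
    # self-alignment formats as 1.0000
    self_aln = align_pair(q, q)
    write_results([self_aln], out)
    assert "\t1.0000\t1.0000\t" in out.read_text().splitlines()[1]


def test_write_empty_results_header_only(tmp_path):
    out = tmp_path / "empty.tsv"
    write_results([], out)
    assert out.read_text().splitlines() == [
        "#query_id\ttarget_id\tn_query_chains\tn_target_chains\tassignment\t"
        "aligned_residues\tqtm\tttm\trotation\ttranslation"
    ]


def test_read_cluster_map(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("# comment\nrepA\trepA\nrepA\tm1\nrepB\trepB\n")
    assert read_cluster_map(path) == {"repA": ["repA", "m1"], "repB": ["repB"]}


def test_cli_pair_and_fixtures(tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        main, ["fixtures", "--out", str(tmp_path), "--seed", "42"]
    )
    assert result.exit_code == 0, result.output
    pdbs = sorted(p.name for p in tmp_path.glob("*.pdb"))
    assert pdbs == ["fx42q.pdb", "fx42t.pdb"]
    result = runner.invoke(
        main, ["pair", str(tmp_path / "fx42q.pdb"), str(tmp_path / "fx42t.pdb")]
    )
    assert result.exit_code == 0, result.output
    fields = result.output.strip().splitlines()[-1].split("\t")
    assert fields[0] == "fx42q" and fields[1] == "fx42t"
    assert float(fields[6]) > 0.9


def test_cli_search(tmp_path):
    qdir = tmp_path / "q"
    tdir = tmp_path / "t"
    qdir.mkdir()
    tdir.mkdir()
    spec = random_fixture_spec(800, n_chains=2, noise_sigma=0.2)
    q, t, _, _ = make_complex_pair(spec)
    write_pdb(q, qdir / "query.pdb")
    write_pdb(t, tdir / "target.pdb")
    out = tmp_path / "out.tsv"
    runner = CliRunner()
    result = runner.invoke(
        main, ["search", str(qdir), str(tdir), str(out), "--threshold", "0.5"]
    )
    assert result.exit_code == 0, result.output
    rows = parse_results(out)
    assert len(rows) == 1 and rows[0]["target_id"] == "target"
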