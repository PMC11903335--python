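"""Pairwise mode, database search, clustered-database expansion, TSV I/O, CLI.

The end-to-end pipeline for one complex pair: align every query chain against
every target chain, build and normalize the superposition-vector matrix,
cluster it to obtain candidate chain assignments, and report the best-scoring
valid assignment as a :class:`~multimeralign.complex_score.ComplexAlignment`.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np

from .chain_align import AlignConfig, align_chains
from .cluster_assign import iterative_cluster
from .complex_score import REPORT_THRESHOLD, ComplexAlignment, best_alignment
from .structures import ComplexStructure, StructureError, read_structure
from .superposition_matrix import prepare_matrix

__all__ = [
    "align_pair",
    "search_database",
    "search_clustered",
    "write_results",
    "parse_results",
    "read_cluster_map",
    "main",
]

logger = logging.getLogger("multimeralign")

EXPAND_THRESHOLD = 0.3  # permissive TM cutoff for expanding clusters during search


def align_pair(
    Q: ComplexStructure,
    T: ComplexStructure,
    config: AlignConfig | None = None,
    alignments=None,
) -> ComplexAlignment | None:
    """Full complex-to-complex alignment of one pair.

    ``alignments`` may supply externally computed chain alignments (with chain
    indices set); otherwise every chain pair is aligned here. Returns None if
    no chain pair is alignable.
    """
    if alignments is None:
        alignments = []
        for qi, q_chain in enumerate(Q.chains):
            for ti, t_chain in enumerate(T.chains):
                aln = align_chains(
                    q_chain, t_chain, config, query_chain_index=qi, target_chain_index=ti
                )
                if aln is not None:
                    alignments.append(aln)
    if not alignments:
        return None
    matrix = prepare_matrix(alignments)
    candidates = iterative_cluster(matrix, len(Q.chains), len(T.chains))
    return best_alignment(Q, T, candidates, alignments)


def _length_gate(Q: ComplexStructure, T: ComplexStructure, ratio: float = 3.0) -> bool:
    """True if the pair is hopeless: every query chain is more than ``ratio``
    times longer or shorter than every target chain."""
    for q_chain in Q.chains:
        for t_chain in T.chains:
            r = len(q_chain) / len(t_chain)
            if 1.0 / ratio <= r <= ratio:
                return False
    return True


def search_database(
    queries: list[ComplexStructure],
    targets: list[ComplexStructure],
    threshold: float = REPORT_THRESHOLD,
    include_monomers: bool = False,
    prescreen: bool = False,
    score_mode: str = "max",
    config: AlignConfig | None = None,
) -> list[ComplexAlignment]:
    """All queries against all targets; hits with score >= threshold, ranked
    per query by descending score.

    Monomeric targets are rejected for multimeric queries unless
    ``include_monomers``. The optional pre-screen only skips pairs whose chain
    lengths are mutually incompatible (> 3x apart everywhere) and cannot drop
    a genuine hit.
    """
    results: list[ComplexAlignment] = []
    for query in queries:
        hits: list[ComplexAlignment] = []
        for target in targets:
            if len(target.chains) == 1 and len(query.chains) > 1 and not include_monomers:
                continue
            if prescreen and _length_gate(query, target):
                continue
            try:
                aln = align_pair(query, target, config)
            except StructureError as exc:  # pragma: no cover - defensive
                logger.warning("skipping %s vs %s: %s", query.complex_id, target.complex_id, exc)
                continue
            if aln is not None and aln.score(score_mode) >= threshold:
                hits.append(aln)
        hits.sort(key=lambda a: (-a.score(score_mode), a.target_id))
        results.extend(hits)
    return results


def read_cluster_map(path) -> dict[str, list[str]]:
    """Two-column TSV (representative_id, member_id) -> {rep: [members...]}."""
    mapping: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
        mapping.setdefault(fields[0], []).append(fields[1])
    return mapping


def search_clustered(
    queries: list[ComplexStructure],
    representatives: list[ComplexStructure],
    cluster_map: dict[str, list[str]],
    member_structures: dict[str, ComplexStructure],
    expand_threshold: float = EXPAND_THRESHOLD,
    threshold: float = REPORT_THRESHOLD,
    include_monomers: bool = False,
    score_mode: str = "max",
    config: AlignConfig | None = None,
) -> list[ComplexAlignment]:
    """Two-phase clustered-database search.

    Phase 1 aligns queries against the representatives; clusters whose
    representative scores >= ``expand_threshold`` (a failed alignment counts
    as 0) are expanded and all their members aligned in phase 2. The union of
    both phases is filtered by ``threshold`` and ranked as in
    :func:`search_database`. With ``expand_threshold`` 0 every cluster expands
    and the result equals an exhaustive search.
    """
    rep_by_id = {r.complex_id: r for r in representatives}
    results: list[ComplexAlignment] = []
    for query in queries:
        hits: dict[str, ComplexAlignment] = {}

        def consider(target: ComplexStructure) -> float:
            if len(target.chains) == 1 and len(query.chains) > 1 and not include_monomers:
                return 0.0
            aln = align_pair(query, target, config)
            if aln is None:
                return 0.0
            if aln.score(score_mode) >= threshold:
                hits[target.complex_id] = aln
            return aln.score(score_mode)

        for rep in representatives:
            rep_score = consider(rep)
            if rep_score >= expand_threshold:
                for member_id in cluster_map.get(rep.complex_id, []):
                    if member_id == rep.complex_id or member_id in hits:
                        continue
                    member = member_structures.get(member_id)
                    if member is None:
                        logger.warning("cluster member %s has no structure; skipped", member_id)
                        continue
                    if member.complex_id in rep_by_id and member.complex_id != rep.complex_id:
                        pass  # a member may itself be a representative elsewhere
                    consider(member)
        ranked = sorted(hits.values(), key=lambda a: (-a.score(score_mode), a.target_id))
        results.extend(ranked)
    return results


_TSV_HEADER = (
    "#query_id\ttarget_id\tn_query_chains\tn_target_chains\tassignment\t"
    "aligned_residues\tqtm\tttm\trotation\ttranslation"
)


def write_results(results: list[ComplexAlignment], path) -> None:
    """Write alignments as a tab-separated table (header line prefixed '#')."""
    lines = [_TSV_HEADER]
    for a in results:
        rot = ",".join(f"{v:.6f}" for v in a.transform.rotation.ravel())
        trans = ",".join(f"{v:.3f}" for v in a.transform.translation)
        n_q = len({p[0] for p in a.chain_pairs})
        lines.append(
            f"{a.query_id}\t{a.target_id}\t{n_q}\t{len(a.chain_pairs)}\t{a.assignment}\t"
            f"{a.aligned_residues}\t{a.tm_query_norm:.4f}\t{a.tm_target_norm:.4f}\t{rot}\t{trans}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_results(path) -> list[dict]:
    """Parse a results TSV back into dictionaries (formatting precision)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        out.append(
            {
                "query_id": f[0],
                "target_id": f[1],
                "n_query_chains": int(f[2]),
                "n_target_chains": int(f[3]),
                "assignment": f[4],
                "aligned_residues": int(f[5]),
                "qtm": float(f[6]),
                "ttm": float(f[7]),
                "rotation": np.array([float(x) for x in f[8].split(",")]).reshape(3, 3),
                "translation": np.array([float(x) for x in f[9].split(",")]),
            }
        )
    return out


def _load_dir(path) -> list[ComplexStructure]:
    path = Path(path)
    if path.is_file():
        return [read_structure(path)]
    structures = []
    for p in sorted(path.iterdir()):
        if p.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif"):
            try:
                structures.append(read_structure(p))
            except StructureError as exc:
                logger.warning("skipping %s: %s", p, exc)
    return structures


@click.group()
@click.option("-v", "--verbose", count=True, help="-v info, -vv debug (to stderr).")
def main(verbose: int) -> None:
    """mm-align: protein complex alignment via superposition-vector clustering."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbose, 2)]
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")


@main.command()
@click.argument("query", type=click.Path(exists=True))
@click.argument("target", type=click.Path(exists=True))
def pair(query: str, target: str) -> None:
    """Align one query complex against one target complex; TSV row to stdout."""
    try:
        q = read_structure(query)
        t = read_structure(target)
    except StructureError as exc:
        click.echo(str(exc), err=True)
        sys.exit(1)
    aln = align_pair(q, t)
    click.echo(_TSV_HEADER)
    if aln is None:
        click.echo(f"{q.complex_id}\t{t.complex_id}\tno-alignment", err=True)
        return
    rot = ",".join(f"{v:.6f}" for v in aln.transform.rotation.ravel())
    trans = ",".join(f"{v:.3f}" for v in aln.transform.translation)
    click.echo(
        f"{aln.query_id}\t{aln.target_id}\t{len(q.chains)}\t{len(t.chains)}\t{aln.assignment}\t"
        f"{aln.aligned_residues}\t{aln.tm_query_norm:.4f}\t{aln.tm_target_norm:.4f}\t{rot}\t{trans}"
    )


@main.command()
@click.argument("query_dir", type=click.Path(exists=True))
@click.argument("target_dir", type=click.Path(exists=True))
@click.argument("out_tsv", type=click.Path())
@click.option("--threshold", default=REPORT_THRESHOLD, show_default=True)
@click.option("--include-monomers", is_flag=True, help="Keep monomeric targets for multimer queries.")
@click.option("--prescreen", is_flag=True, help="Skip length-incompatible pairs.")
def search(query_dir, target_dir, out_tsv, threshold, include_monomers, prescreen) -> None:
    """Search query complexes against a database directory."""
    queries = _load_dir(query_dir)
    targets = _load_dir(target_dir)
    results = search_database(
        queries, targets, threshold=threshold,
        include_monomers=include_monomers, prescreen=prescreen,
    )
    write_results(results, out_tsv)
    click.echo(f"{len(results)} hits written to {out_tsv}", err=True)


@main.command("search-clustered")
@click.argument("query_dir", type=click.Path(exists=True))
@click.argument("rep_dir", type=click.Path(exists=True))
@click.argument("members_tsv", type=click.Path(exists=True))
@click.argument("out_tsv", type=click.Path())
@click.option("--member-dir", type=click.Path(exists=True), default=None,
              help="Directory with member structures (defaults to REP_DIR).")
@click.option("--expand-threshold", default=EXPAND_THRESHOLD, show_default=True)
@click.option("--threshold", default=REPORT_THRESHOLD, show_default=True)
@click.option("--include-monomers", is_flag=True)
def search_clustered_cmd(
    query_dir, rep_dir, members_tsv, out_tsv, member_dir, expand_threshold, threshold,
    include_monomers,
) -> None:
    """Search a clustered database: representatives first, then promising clusters."""
    queries = _load_dir(query_dir)
    representatives = _load_dir(rep_dir)
    members = _load_dir(member_dir) if member_dir else representatives
    member_structures = {s.complex_id: s for s in representatives + members}
    cluster_map = read_cluster_map(members_tsv)
    results = search_clustered(
        queries, representatives, cluster_map, member_structures,
        expand_threshold=expand_threshold, threshold=threshold,
        include_monomers=include_monomers,
    )
    write_results(results, out_tsv)
    click.echo(f"{len(results)} hits written to {out_tsv}", err=True)


@main.command()
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--spec", "spec_json", type=click.Path(exists=True), default=None,
              help="JSON with n_chains / chain_lengths / noise_sigma overrides.")
def fixtures(out_dir, seed, spec_json) -> None:
    """Generate a synthetic complex pair with ground-truth JSON."""
    from .fixtures import FixtureSpec, random_fixture_spec, write_fixture

    if spec_json:
        raw = json.loads(Path(spec_json).read_text())
        base = random_fixture_spec(
            raw.get("seed", seed),
            n_chains=raw.get("n_chains"),
            noise_sigma=raw.get("noise_sigma", 0.5),
        )
        if "chain_lengths" in raw:
            base = FixtureSpec(
                base.n_chains, list(raw["chain_lengths"]), base.inter_chain_transforms,
                base.noise_sigma, base.chain_permutation, base.seed,
            )
        spec = base
    else:
        spec = random_fixture_spec(seed)
    truth = write_fixture(spec, out_dir)
    click.echo(json.dumps(truth, indent=2))


if __name__ == "__main__":  # pragma: no cover
    main()
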