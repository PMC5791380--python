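"""End-to-end analysis: classify → group → pair → metrics → statistics.

Reads a manifest (or a directory) of PDB conformers, labels each one's
crystallization environment, applies quality control, forms same-protein
conformer groups, selects the maximum-RMSD pair per subgroup, computes the
structural metric panel and pairwise deltas, and compares the subgroup
distributions. All outputs are deterministic for a fixed input and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .environment import (
    ConformerPair,
    SolventLexicon,
    Subgroup,
    default_additives,
    detect_bound,
    enumerate_pairs,
    group_by_sequence,
    label_environment,
    load_additives,
    qc_filter,
    select_max_pair,
)
from .io import parse_pdb
from .metrics import active_site_metrics, compute_panel, pair_deltas
from .model import Structure
from .secondary import ss_element_rmsd
from .stats import ComparisonReport, compare_subgroups
from .superpose import pair_rmsd

log = logging.getLogger(__name__)


class NoDataError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input_path: str | Path = "."          # manifest TSV or directory of PDBs
    lexicon_path: str | Path | None = None
    additives_path: str | Path | None = None
    catalytic_sites_path: str | Path | None = None
    max_resolution: float = 4.0
    exclude_mutants: bool = True
    buried_threshold: float = 25.0
    idr_min_length: int = 5
    idr_terminal_exclusion: int = 20
    alpha: float = 0.05
    asa_probe: float = 1.4
    asa_points: int = 960
    cavity_grid_spacing: float = 0.8
    cavity_probe: float = 1.4
    cavity_min_volume: float = 30.0
    with_cavities: bool = True
    seed: int = 0
    output_dir: str | Path | None = None

    def lexicon(self) -> SolventLexicon:
        if self.lexicon_path is None:
            return SolventLexicon.default()
        return SolventLexicon.from_file(self.lexicon_path)

    def additives(self) -> set[str]:
        if self.additives_path is None:
            return default_additives()
        return load_additives(self.additives_path)


@dataclass
class RunResult:
    report: ComparisonReport
    conformer_panel: pd.DataFrame
    all_pairs: pd.DataFrame
    max_pairs: pd.DataFrame
    qc_log: pd.DataFrame
    cavity_table: pd.DataFrame | None = None


def load_inputs(config: RunConfig) -> list[tuple[str | None, Structure]]:
    """(protein_id, structure) tuples from a manifest TSV or a directory."""
    path = Path(config.input_path)
    entries: list[tuple[str | None, Structure]] = []
    if path.is_dir():
        manifest = path / "manifest.tsv"
        if manifest.exists():
            import dataclasses

            return load_inputs(dataclasses.replace(config, input_path=manifest))
        for pdb_path in sorted(path.glob("*.pdb")):
            st = parse_pdb(pdb_path.read_text(), id=pdb_path.stem)
            entries.append((None, st))
    else:
        df = pd.read_csv(path, sep="\t")
        base = path.parent
        for _, row in df.iterrows():
            pdb_path = Path(row["pdb_path"])
            if not pdb_path.is_absolute():
                pdb_path = base / pdb_path
            chain = str(row["chain"]) if "chain" in df.columns else None
            st = parse_pdb(pdb_path.read_text(), chain_filter=chain,
                           id=pdb_path.stem)
            if "has_mutations" in df.columns:
                st.has_mutations = bool(int(row["has_mutations"]))
            entries.append((str(row["protein_id"]), st))
    if not entries:
        raise NoDataError(f"no PDB inputs under {path}")
    return entries


def _load_sites(path: str | Path | None) -> dict[str, list[tuple[str, int]]]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep="\t")
    sites: dict[str, list[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        sites.setdefault(str(row["protein_id"]), []).append(
            (str(row["chain"]), int(row["seq_num"])))
    return sites


def run_analysis(config: RunConfig) -> RunResult:
    lexicon = config.lexicon()
    additives = config.additives()
    sites = _load_sites(config.catalytic_sites_path)

    entries = load_inputs(config)
    structures = [st for _, st in entries]
    kept = qc_filter(structures, config.max_resolution, config.exclude_mutants)
    kept_ids = {s.id for s in kept}
    qc_rows = [
        {"id": st.id, "resolution": st.resolution,
         "has_mutations": st.has_mutations,
         "status": "kept" if st.id in kept_ids else "rejected"}
        for _, st in entries
    ]
    log.info("QC: %d of %d structures kept", len(kept), len(entries))

    by_protein: dict[str, list[Structure]] = {}
    if any(pid is not None for pid, _ in entries):
        for pid, st in entries:
            if st.id in kept_ids:
                by_protein.setdefault(pid, []).append(st)
        groups = [sorted(g, key=lambda s: s.id)
                  for _, g in sorted(by_protein.items()) if len(g) >= 2]
        group_ids = [pid for pid, g in sorted(by_protein.items()) if len(g) >= 2]
    else:
        groups = group_by_sequence(kept)
        group_ids = [f"g{i:03d}" for i in range(len(groups))]
    if not groups:
        raise NoDataError("no conformer group with >= 2 structures after QC")

    labels = {s.id: label_environment(s, lexicon) for s in kept}
    bound = {s.id: detect_bound(s, lexicon, additives) for s in kept}

    panel_cache: dict[str, object] = {}

    def panel(st: Structure):
        if st.id not in panel_cache:
            panel_cache[st.id] = compute_panel(
                st, config.asa_probe, config.asa_points,
                with_cavities=config.with_cavities,
                cavity_kwargs={
                    "grid_spacing": config.cavity_grid_spacing,
                    "probe": config.cavity_probe,
                    "min_volume": config.cavity_min_volume,
                },
            )
        return panel_cache[st.id]

    pair_rows = []
    max_rows = []
    for pid, group in zip(group_ids, groups):
        pairs = enumerate_pairs(group, labels, bound)
        for p in pairs:
            pair_rows.append({
                "protein_id": pid, "conf_a": p.conf_a.id, "conf_b": p.conf_b.id,
                "subgroup": p.subgroup.value, "bound_state": p.bound_state,
                "rmsd": p.rmsd,
            })
        for sg in Subgroup:
            mp = select_max_pair(pairs, sg)
            if mp is None:
                continue
            max_rows.append(_max_pair_row(pid, mp, panel, sites.get(pid)))

    for _, st in entries:
        if st.id in kept_ids and st.id not in panel_cache:
            panel(st)

    panel_df = pd.DataFrame(
        sorted((panel_cache[i].row() for i in panel_cache),
               key=lambda r: r["id"])
    )
    pairs_df = pd.DataFrame(pair_rows)
    max_df = pd.DataFrame(max_rows)
    if max_df.empty:
        raise NoDataError("no maximum pairs could be formed")

    metrics = ["rmsd", "d_global_asa", "d_relative_asa", "d_hbonds", "d_rg",
               "d_n_idr_regions", "d_missing_fraction",
               "helix_rmsd", "sheet_rmsd", "loop_rmsd"]
    if config.with_cavities:
        metrics += ["d_total_cavity_volume", "d_n_cavities"]
    if sites:
        metrics += ["site_rmsd", "site_rel_asa_diff"]
    metrics = [m for m in metrics if m in max_df.columns]
    report = compare_subgroups(max_df, metrics, alpha=config.alpha)

    cavity_df = None
    if config.with_cavities:
        cavity_df = panel_df[["id", "n_cavities", "total_cavity_volume",
                              "max_cavity_volume", "cavity_flexibility"]]

    result = RunResult(report, panel_df, pairs_df, max_df,
                       pd.DataFrame(qc_rows), cavity_df)
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _max_pair_row(pid: str, mp: ConformerPair, panel_fn, site) -> dict:
    pr = pair_rmsd(mp.conf_a, mp.conf_b)
    pa, pb = panel_fn(mp.conf_a), panel_fn(mp.conf_b)
    deltas = pair_deltas(pa, pb)
    # SS classes taken from conformer A (the lexicographically first id)
    elem = ss_element_rmsd(pr.per_site_map(), pa.ss)
    row = {
        "protein_id": pid, "conf_a": mp.conf_a.id, "conf_b": mp.conf_b.id,
        "subgroup": mp.subgroup.value, "bound_state": mp.bound_state,
        "rmsd": mp.rmsd,
        "helix_rmsd": elem.get("H"), "sheet_rmsd": elem.get("E"),
        "loop_rmsd": elem.get("L"),
        **deltas.row(),
    }
    if site:
        row.update(active_site_metrics(pr, pa.asa, pb.asa, site))
    return row


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.conformer_panel.to_csv(out_dir / "conformer_panel.tsv", sep="\t",
                                  index=False, float_format="%.4f")
    result.all_pairs.to_csv(out_dir / "pairs.tsv", sep="\t", index=False,
                            float_format="%.4f")
    result.max_pairs.to_csv(out_dir / "max_pairs.tsv", sep="\t", index=False,
                            float_format="%.4f")
    result.qc_log.to_csv(out_dir / "qc_log.tsv", sep="\t", index=False)
    if result.cavity_table is not None:
        result.cavity_table.to_csv(out_dir / "cavities.tsv", sep="\t",
                                   index=False, float_format="%.4f")
    (out_dir / "report.json").write_text(result.report.to_json())
    (out_dir / "report.txt").write_text(report_render(result.report))


def report_render(report: ComparisonReport) -> str:
    """Human-readable summary mirroring the subgroup comparison layout."""
    def fmt(v, spec="{:.3f}"):
        return "n/a" if v is None else spec.format(v)

    lines = [
        "Subgroup comparison report "
        f"(significance at p < {report.alpha:g})",
        "=" * 72,
    ]
    for metric in sorted(report.metrics):
        entry = report.metrics[metric]
        lines.append(f"\n{metric}")
        lines.append(f"  {'subgroup':<10}{'n':>6}{'mean':>12}{'median':>12}")
        for sg in ("AA", "AO", "OO"):
            s = entry["subgroups"].get(sg) or {}
            lines.append(
                f"  {sg:<10}{fmt(s.get('n'), '{:d}'):>6}"
                f"{fmt(s.get('mean')):>12}{fmt(s.get('median')):>12}"
            )
        for name, ks in entry["ks"].items():
            if ks is None:
                lines.append(f"  KS {name:<10}: n/a")
            else:
                star = " *" if ks["significant"] else ""
                lines.append(
                    f"  KS {name:<10}: D={ks['D']:.3f} p={ks['p']:.3g}{star}")
        an = entry["anova"]
        if an is None:
            lines.append("  ANOVA: n/a")
        else:
            star = " *" if an["significant"] else ""
            lines.append(f"  ANOVA: F={an['F']:.3f} p={an['p']:.3g}{star}")
    return "\n".join(lines) + "\n"
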