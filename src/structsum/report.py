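"""The controlling pipeline: run every analysis on each input
structure, pre-generate all data files, images and static HTML pages,
and maintain the run index plus the append-only run registry.

Output layout, per entry code under the output directory:

    <out>/index.html            current-run index
    <out>/all_runs.html         registry page of every prior run
    <out>/runs.tsv              append-only registry (code, timestamp,
                                source, output path)
    <out>/<code>/main.html      content summary + links
    <out>/<code>/*.html,*.tsv,*.svg,*.json, view.spt, view.pml, ...

Everything except the registry timestamps is byte-reproducible for a
given input set, configuration, and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from structsum import clefts as clefts_mod
from structsum import contacts as contacts_mod
from structsum import interfaces as interfaces_mod
from structsum import ligplot2d
from structsum import secstruct as ss_mod
from structsum import stereochem as st_mod
from structsum.config import Config
from structsum.pdb_io import (Structure, assign_pdb_code, classify_chains,
                              coverage_count, parse_pdb_file, write_pdb)

logger = logging.getLogger(__name__)


@dataclass
class RunRecord:
    code: str
    source: str
    timestamp: str
    out_dir: Path
    thumbnail: str = "thumbnail.svg"
    error: Optional[str] = None
    notes: list = field(default_factory=list)   # analyses that failed


# ---------------------------------------------------------------------------
# registry

def read_registry(out_dir: Path) -> list[dict]:
    reg = out_dir / "runs.tsv"
    rows = []
    if reg.exists():
        for line in reg.read_text().splitlines()[1:]:
            parts = line.split("\t")
            if len(parts) >= 4:
                rows.append(dict(code=parts[0], timestamp=parts[1],
                                 source=parts[2], path=parts[3]))
    return rows


def append_registry(out_dir: Path, records: list[RunRecord]) -> None:
    reg = out_dir / "runs.tsv"
    lines = []
    if not reg.exists():
        lines.append("code\ttimestamp\tsource\tpath")
    for r in records:
        if r.error is None:
            lines.append(f"{r.code}\t{r.timestamp}\t{r.source}\t{r.code}/")
    if lines:
        with open(reg, "a") as fh:
            fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(inputs: Iterable, out_dir, config: Config = None,
                 codes: Optional[dict] = None, skip: Iterable[str] = (),
                 force: bool = False) -> list[RunRecord]:
    """Process each input file: parse, run all analyses, emit pages.

    *codes* maps input path -> explicit 4-character code. *skip* names
    analysis stages to leave out (e.g. {"clefts", "ligplot"}). A
    structure whose output is already complete is not recomputed
    unless *force* is set; failed inputs produce error records."""
    cfg = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skip = set(skip)
    codes = codes or {}
    registry_rows = read_registry(out)
    used_codes = {row["code"] for row in registry_rows}
    code_by_source = {row["source"]: row["code"] for row in registry_rows}

    records: list[RunRecord] = []
    for path in inputs:
        path = Path(path)
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        try:
            if str(path) in code_by_source and codes.get(str(path)) is None:
                # a source already in the registry keeps its code, so a
                # deleted output directory is simply regenerated
                code = code_by_source[str(path)]
            else:
                code = assign_pdb_code(path, codes.get(str(path)), used_codes)
        except ValueError as exc:
            records.append(RunRecord(code="????", source=str(path), timestamp=stamp,
                                     out_dir=out, error=str(exc)))
            continue
        used_codes.add(code)
        entry_dir = out / code
        marker = entry_dir / ".complete"
        if marker.exists() and not force:
            records.append(RunRecord(code=code, source=str(path), timestamp=stamp,
                                     out_dir=entry_dir))
            continue
        try:
            structure = parse_pdb_file(path, code=code)
        except Exception as exc:  # unreadable/empty input: error record
            logger.error("%s: %s", path, exc)
            records.append(RunRecord(code=code, source=str(path), timestamp=stamp,
                                     out_dir=entry_dir, error=str(exc)))
            continue
        record = RunRecord(code=code, source=str(path), timestamp=stamp,
                           out_dir=entry_dir)
        try:
            process_structure(structure, entry_dir, cfg, skip, record)
            marker.write_text("ok\n")
        except Exception as exc:
            logger.exception("pipeline failed for %s", path)
            record.error = str(exc)
        records.append(record)
    already = {row["code"] for row in read_registry(out)}
    append_registry(out, [r for r in records
                          if r.error is None and r.code not in already])
    generate_index(records, out)
    return records


def process_structure(s: Structure, entry_dir: Path, cfg: Config,
                      skip: set, record: RunRecord) -> None:
    entry_dir.mkdir(parents=True, exist_ok=True)
    t_all = time.time()
    log_lines = []

    def stage(name):
        def wrapper(fn):
            t0 = time.time()
            try:
                result = fn()
                log_lines.append(f"{name}\tok\t{time.time() - t0:.2f}s")
                return result
            except Exception as exc:
                logger.exception("%s failed on %s", name, s.code)
                record.notes.append(f"{name} failed: {exc}")
                log_lines.append(f"{name}\tFAILED\t{time.time() - t0:.2f}s")
                return None
        return wrapper

    (entry_dir / "structure.pdb").write_text(write_pdb(s))

    contact_set = stage("contacts")(lambda: contacts_mod.analyse_contacts(s, cfg.contacts))
    if contact_set is not None:
        (entry_dir / "hbonds.tsv").write_text(contacts_mod.hbonds_table(contact_set.hbonds))
        (entry_dir / "nonbonded.tsv").write_text(
            contacts_mod.contacts_table(contact_set.nonbonded))
        (entry_dir / "saltbridges.tsv").write_text(
            contacts_mod.salt_bridges_table(contact_set.salt_bridges))
        (entry_dir / "metals.tsv").write_text(
            contacts_mod.contacts_table(contact_set.metals, "metal"))

    assignment = stage("secstruct")(lambda: ss_mod.assign_secondary_structure(s))
    turns = []
    gammas = []
    if assignment is not None:
        (entry_dir / "secstruct.tsv").write_text(ss_mod.secstruct_table(assignment))
        turns = ss_mod.find_beta_turns(s, assignment)
        (entry_dir / "turns.tsv").write_text(ss_mod.turns_table(turns))
        if contact_set is not None:
            gammas = ss_mod.find_gamma_turns(s, assignment, contact_set.hbonds)
        motifs = {
            "hairpins": [vars_motif(h) for h in ss_mod.find_hairpins(assignment)],
            "bulges": [vars_motif(b) for b in ss_mod.find_bulges(assignment)],
            "beta_alpha_beta": [vars_motif(u) for u in ss_mod.find_beta_alpha_beta(assignment)],
            "psi_loops": [vars_motif(p) for p in ss_mod.find_psi_loops(assignment)],
            "helix_packing": [vars_motif(p) for p in
                              ss_mod.find_helix_interactions(s, assignment,
                                                             cfg.helix_pack_cutoff)],
            "gamma_turns": [vars_motif(g) for g in gammas],
        }
        (entry_dir / "motifs.json").write_text(json.dumps(motifs, indent=1,
                                                          default=_json_default))

    torsions = stage("stereochem")(lambda: st_mod.compute_structure_torsions(s))
    sasa_result = None
    if "sasa" not in skip:
        sasa_result = stage("sasa")(
            lambda: interfaces_mod.sasa(s, cfg.sasa.probe, cfg.sasa.n_points))
    if torsions is not None:
        deviations = st_mod.check_geometry(s, cfg.stereo) + st_mod.check_planarity(s, cfg.stereo)
        gfactors = st_mod.compute_g_factors(torsions)
        props = st_mod.residue_property_profile(s, torsions, assignment, sasa_result,
                                                cfg.stereo)
        (entry_dir / "procheck_summary.txt").write_text(
            st_mod.procheck_summary(torsions, gfactors, deviations))
        (entry_dir / "distorted_geometry.tsv").write_text(
            st_mod.deviations_table(deviations))
        (entry_dir / "residue_properties.tsv").write_text(st_mod.properties_table(props))
        (entry_dir / "ramachandran.svg").write_text(
            st_mod.ramachandran_svg(torsions, s.code))

    chain_types = classify_chains(s)
    protein_chains = [c for c, t in chain_types.items() if t == "protein"]
    summaries = []
    if contact_set is not None and "interfaces" not in skip:
        for i, ca in enumerate(protein_chains):
            for cb in protein_chains[i + 1:]:
                summ = stage(f"interface {ca}-{cb}")(
                    lambda ca=ca, cb=cb: interfaces_mod.analyze_interface(
                        s, ca, cb, contact_set, cfg.sasa))
                if summ is not None:
                    summaries.append(summ)
                    (entry_dir / f"interface_{ca}{cb}.tsv").write_text(
                        interfaces_mod.interface_table(summ))
                    (entry_dir / f"interface_{ca}{cb}.json").write_text(
                        json.dumps(interfaces_mod.interface_diagram_data(summ),
                                   indent=1))
        (entry_dir / "interface_summary.tsv").write_text(
            interfaces_mod.interface_summary_table(summaries))

    cleft_list = []
    if "clefts" not in skip:
        result = stage("clefts")(
            lambda: clefts_mod.compute_clefts(s, params=cfg.clefts))
        if result is not None:
            cleft_list, _grid = result
            (entry_dir / "clefts.tsv").write_text(clefts_mod.clefts_table(cleft_list))
            clefts_mod.write_cleft_outputs(cleft_list, entry_dir, "structure.pdb")

    lig_pages = []
    if contact_set is not None and "ligplot" not in skip:
        for lig in s.het_groups():
            if len(lig.heavy_atoms()) < 2 and lig.category != "metal":
                continue
            safe = f"{lig.resname}_{lig.chain_id}{lig.resseq}"
            graph = stage(f"ligplot {safe}")(
                lambda lig=lig: ligplot2d.build_interaction_graph(s, lig, contact_set))
            if graph is None:
                continue
            layout = ligplot2d.flatten_layout(graph, seed=cfg.seed)
            (entry_dir / f"ligplot_{safe}.svg").write_text(
                ligplot2d.render_svg(graph, layout))
            (entry_dir / f"ligplot_{safe}.tsv").write_text(
                ligplot2d.interactions_table(graph))
            lig_pages.append((lig, safe, graph, layout))

    if assignment is not None:
        lig_contact_keys = set()
        if contact_set is not None:
            for hb in contact_set.hbonds:
                if hb.category == "protein-ligand":
                    for ref in (hb.donor, hb.acceptor):
                        if ref.residue.category == "amino":
                            lig_contact_keys.add(ref.residue.key)
            for c in contact_set.nonbonded:
                cats = {c.atom_a.residue.category, c.atom_b.residue.category}
                if "ligand" in cats or "metal" in cats:
                    for ref in (c.atom_a, c.atom_b):
                        if ref.residue.category == "amino":
                            lig_contact_keys.add(ref.residue.key)
        wiring = ss_mod.wiring_diagram_data(s, assignment, turns, gammas,
                                            lig_contact_keys)
        (entry_dir / "wiring.json").write_text(json.dumps(wiring, indent=1))

    (entry_dir / "thumbnail.svg").write_text(thumbnail_svg(s))
    write_viewer_scripts(s, turns, cleft_list, entry_dir)
    write_pages(s, entry_dir, record, chain_types, summaries, lig_pages,
                turns, cleft_list)
    log_lines.append(f"total\t\t{time.time() - t_all:.2f}s")
    (entry_dir / "run.log").write_text("\n".join(log_lines) + "\n")


def vars_motif(m) -> dict:
    d = {}
    for k, v in vars(m).items():
        d[k] = v
    return d


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)


# ---------------------------------------------------------------------------
# thumbnail

CHAIN_COLOURS = ["#7744aa", "#cc3333", "#3366cc", "#33aa55", "#cc8822", "#22aaaa"]


def thumbnail_svg(s: Structure, size: int = 160) -> str:
    """CA-trace (or all-atom) orthographic projection coloured by chain."""
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}">']
    traces = []
    points_all = []
    for chain in s.chains:
        trace = []
        for res in chain.residues:
            a = res.atom("CA") or (res.heavy_atoms()[0] if res.heavy_atoms() else None)
            if a is not None:
                trace.append(a.xyz)
                points_all.append(a.xyz)
        traces.append(trace)
    if not points_all:
        parts.append("</svg>")
        return "\n".join(parts) + "\n"
    pts = np.array(points_all)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = float(max((hi - lo)[:2].max(), 1e-6))
    scale = (size - 20) / span

    def xy(p):
        return ((p[0] - lo[0]) * scale + 10, size - ((p[1] - lo[1]) * scale + 10))

    for ci, trace in enumerate(traces):
        if len(trace) < 2:
            for p in trace:
                x, y = xy(p)
                parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3" '
                             f'fill="{CHAIN_COLOURS[ci % len(CHAIN_COLOURS)]}"/>')
            continue
        path = " ".join(
            ("M" if i == 0 else "L") + f" {xy(p)[0]:.1f} {xy(p)[1]:.1f}"
            for i, p in enumerate(trace)
        )
        parts.append(f'<path d="{path}" fill="none" '
                     f'stroke="{CHAIN_COLOURS[ci % len(CHAIN_COLOURS)]}" '
                     f'stroke-width="2"/>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# viewer scripts

TURN_COLOURS_RASMOL = ["red", "brown", "green", "blue"]


def write_viewer_scripts(s: Structure, turns, cleft_list, entry_dir: Path) -> None:
    """RasMol (.spt) and PyMOL (.pml) scripts: load the coordinates,
    colour chains, and add named scenes for each beta turn (residues
    coloured red/brown/green/blue in order, H-bonds shown) and for the
    clefts (rank 1 red). All paths are relative to the output dir."""
    spt = ["load structure.pdb", "wireframe off", "cartoons on",
           "color chain", "hbonds on"]
    pml = ["load structure.pdb, molecule", "hide everything, molecule",
           "show cartoon, molecule", "util.cbc('molecule')"]
    for t_i, turn in enumerate(turns, start=1):
        spt.append(f"# scene turn{t_i}: beta turn "
                   f"{turn.keys[0][1]}-{turn.keys[3][1]} class {turn.turn_class}")
        pml.append(f"# scene turn{t_i}: beta turn "
                   f"{turn.keys[0][1]}-{turn.keys[3][1]} class {turn.turn_class}")
        for pos, key in enumerate(turn.keys):
            colour = TURN_COLOURS_RASMOL[pos]
            spt.append(f"select {key[1]}:{key[0]}")
            spt.append(f"color {colour}")
            pml.append(f"color {colour}, molecule and chain {key[0]} "
                       f"and resi {key[1]}")
        pml.append(f"scene turn{t_i}, store")
    if cleft_list:
        spt.append("# scene clefts (rank 1 red)")
        for c in cleft_list:
            colour = clefts_mod.CLEFT_COLOURS[(c.rank - 1) % len(clefts_mod.CLEFT_COLOURS)]
            pml.append(f"load cleft_{c.rank}.pdb, cleft{c.rank}")
            pml.append(f"show spheres, cleft{c.rank}")
            pml.append(f"color {colour}, cleft{c.rank}")
            spt.append(f"# cleft {c.rank}: cleft_{c.rank}.pdb -> {colour}")
        pml.append("scene clefts, store")
    (entry_dir / "view.spt").write_text("\n".join(spt) + "\n")
    (entry_dir / "view.pml").write_text("\n".join(pml) + "\n")


# ---------------------------------------------------------------------------
# HTML pages

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; font-size: 13px; }}
nav a {{ margin-right: 1em; }}
</style></head>
<body>
<nav><a href="../index.html">Run index</a>{nav}</nav>
<h1>{title}</h1>
{body}
</body></html>
"""


def _nav(pages: list[tuple[str, str]]) -> str:
    return "".join(f'<a href="{href}">{label}</a>' for href, label in pages)


def write_pages(s: Structure, entry_dir: Path, record: RunRecord,
                chain_types: dict, summaries, lig_pages, turns, cleft_list) -> None:
    pages = [("main.html", "Summary"), ("interfaces.html", "Interfaces"),
             ("secstruct.html", "Secondary structure"),
             ("procheck.html", "Stereochemistry"), ("clefts.html", "Clefts")]
    for lig, safe, _g, _l in lig_pages:
        pages.append((f"ligplot_{safe}.html", f"Ligand {lig.resname}"))
    nav = _nav(pages)

    # main page
    rows = []
    for chain_id, kind in chain_types.items():
        cov = ""
        if kind == "protein":
            obs, dec = coverage_count(s, chain_id)
            cov = f"{obs} of {dec} residues observed"
        rows.append(f"<tr><td>{chain_id}</td><td>{kind}</td><td>{cov}</td></tr>")
    hets = "".join(f"<li>{r.label} ({len(r.heavy_atoms())} atoms, {r.category})</li>"
                   for r in s.het_groups())
    notes = "".join(f"<p><em>Note: {n}</em></p>" for n in record.notes)
    body = f"""
<img src="thumbnail.svg" alt="thumbnail" width="160" height="160"/>
<p><b>Source:</b> {record.source}</p>
<p><b>Title:</b> {s.header.title or '-'}<br/>
<b>Compound:</b> {s.header.compound or '-'}<br/>
<b>Method:</b> {s.header.method or '-'}</p>
<h2>Contents</h2>
<table><tr><th>Chain</th><th>Type</th><th>Coverage</th></tr>{''.join(rows)}</table>
<h2>HET groups</h2><ul>{hets or '<li>none</li>'}</ul>
{notes}
<h2>Data files</h2>
<ul>
<li><a href="hbonds.tsv">Hydrogen bonds</a>, <a href="nonbonded.tsv">non-bonded contacts</a>,
<a href="saltbridges.tsv">salt bridges</a>, <a href="metals.tsv">metal contacts</a></li>
<li><a href="view.spt">RasMol script</a>, <a href="view.pml">PyMOL script</a>,
<a href="structure.pdb">coordinates as parsed</a></li>
</ul>
"""
    (entry_dir / "main.html").write_text(
        _PAGE.format(title=f"Entry {s.code}", nav=nav, body=body))

    # interfaces page
    if summaries:
        tbl = ["<table><tr><th>Chains</th><th>Salt bridges</th><th>H-bonds</th>"
               "<th>Non-bonded</th><th>Disulphides</th><th>Buried area (A&#178;)</th>"
               "<th>Wedge %</th><th>Details</th></tr>"]
        for sm in summaries:
            tbl.append(
                f"<tr><td>{sm.chain_a}-{sm.chain_b}</td><td>{sm.n_salt_bridges}</td>"
                f"<td>{sm.n_hbonds}</td><td>{sm.n_nonbonded}</td>"
                f"<td>{sm.n_disulphides}</td>"
                f"<td>{sm.buried_area_a:.1f} / {sm.buried_area_b:.1f}</td>"
                f"<td>{sm.wedge_percent_a:.1f} / {sm.wedge_percent_b:.1f}</td>"
                f"<td><a href='interface_{sm.chain_a}{sm.chain_b}.tsv'>table</a></td></tr>")
        tbl.append("</table>")
        body = "".join(tbl)
    else:
        body = "<p>No protein chain pairs (or interface analysis skipped).</p>"
    (entry_dir / "interfaces.html").write_text(
        _PAGE.format(title=f"{s.code}: chain-chain interfaces", nav=nav, body=body))

    # secondary structure page
    body = """<p>Per-residue assignment: <a href="secstruct.tsv">secstruct.tsv</a>;
motifs: <a href="motifs.json">motifs.json</a>;
wiring-diagram data: <a href="wiring.json">wiring.json</a>.</p>"""
    if turns:
        rows = "".join(
            f"<tr><td>{t.chain_id}</td><td>{t.keys[0][1]}-{t.keys[3][1]}</td>"
            f"<td>{t.turn_class}</td></tr>" for t in turns)
        body += (f"<h2>Beta turns</h2><table><tr><th>Chain</th><th>Span</th>"
                 f"<th>Class</th></tr>{rows}</table>"
                 f"<p>Full torsions in <a href='turns.tsv'>turns.tsv</a>.</p>")
    (entry_dir / "secstruct.html").write_text(
        _PAGE.format(title=f"{s.code}: secondary structure", nav=nav, body=body))

    # stereochemistry page
    summary_txt = (entry_dir / "procheck_summary.txt")
    summary_html = summary_txt.read_text().replace("\n", "<br/>") if summary_txt.exists() else ""
    body = f"""<img src="ramachandran.svg" alt="Ramachandran plot"/>
<p>{summary_html}</p>
<p><a href="residue_properties.tsv">Residue property profile</a> |
<a href="distorted_geometry.tsv">Distorted geometry records</a></p>"""
    (entry_dir / "procheck.html").write_text(
        _PAGE.format(title=f"{s.code}: stereochemical quality", nav=nav, body=body))

    # clefts page
    if cleft_list:
        rows = "".join(
            f"<tr><td>{c.rank}</td><td>{c.volume:.1f}</td><td>{len(c.voxels)}</td>"
            f"<td><a href='cleft_{c.rank}.pdb'>voxels</a></td></tr>"
            for c in cleft_list)
        body = (f"<table><tr><th>Rank</th><th>Volume (A&#179;)</th><th>Voxels</th>"
                f"<th>File</th></tr>{rows}</table>"
                f"<p>Viewer scripts: <a href='clefts.spt'>RasMol</a>, "
                f"<a href='clefts.pml'>PyMOL</a> (largest cleft coloured red). "
                f"Summary: <a href='clefts.tsv'>clefts.tsv</a>.</p>")
    else:
        body = "<p>No clefts above the minimum volume (or stage skipped).</p>"
    (entry_dir / "clefts.html").write_text(
        _PAGE.format(title=f"{s.code}: surface clefts", nav=nav, body=body))

    # per-ligand pages
    for lig, safe, graph, layout in lig_pages:
        conv = "" if layout.converged else \
            f"<p><em>Layout did not fully converge: {layout.overlap_count} overlaps.</em></p>"
        body = f"""<img src="ligplot_{safe}.svg" alt="2D interaction diagram"/>
{conv}
<p>{len(graph.hbonds)} hydrogen bond(s), {len(graph.eyelashes)} residue(s) in
non-bonded contact only. Interaction list:
<a href="ligplot_{safe}.tsv">ligplot_{safe}.tsv</a></p>"""
        (entry_dir / f"ligplot_{safe}.html").write_text(
            _PAGE.format(title=f"{s.code}: ligand {lig.label}", nav=nav, body=body))


def generate_index(records: list[RunRecord], out_dir: Path) -> None:
    """Write the current-run index and the all-runs registry page."""
    rows = []
    for r in records:
        if r.error is not None:
            rows.append(f"<tr><td>{r.code}</td><td>{r.source}</td>"
                        f"<td colspan='2'>ERROR: {r.error}</td></tr>")
        else:
            rows.append(
                f"<tr><td><a href='{r.code}/main.html'>"
                f"<img src='{r.code}/thumbnail.svg' width='80' height='80'/></a></td>"
                f"<td><a href='{r.code}/main.html'>{r.code}</a></td>"
                f"<td>{r.source}</td><td>{r.timestamp}</td></tr>")
    body = f"""<p><a href="all_runs.html"><b>structsum</b></a> &mdash; structures
processed in this run: {sum(1 for r in records if r.error is None)}</p>
<table><tr><th></th><th>Code</th><th>Source</th><th>Processed</th></tr>
{''.join(rows)}</table>
"""
    (out_dir / "index.html").write_text(
        _PAGE.format(title="Run index", nav="", body=body).replace(
            '<nav><a href="../index.html">Run index</a></nav>', "<nav></nav>"))

    reg_rows = "".join(
        f"<tr><td><a href='{row['path']}main.html'>{row['code']}</a></td>"
        f"<td>{row['source']}</td><td>{row['timestamp']}</td></tr>"
        for row in read_registry(out_dir))
    body = f"""<p>All runs recorded in <a href="runs.tsv">runs.tsv</a>.</p>
<table><tr><th>Code</th><th>Source</th><th>Processed</th></tr>{reg_rows}</table>
"""
    (out_dir / "all_runs.html").write_text(
        _PAGE.format(title="All prior runs", nav='<a href="index.html">Current run</a>',
                     body=body).replace(
            '<nav><a href="../index.html">Run index</a>', "<nav>"))


# ---------------------------------------------------------------------------
# link check used by tests and the pipeline's own validation

def check_links(out_dir: Path) -> list[str]:
    """Return the list of broken internal hrefs/srcs under *out_dir*."""
    import re

    broken = []
    for page in Path(out_dir).rglob("*.html"):
        html = page.read_text()
        for m in re.finditer(r'(?:href|src)=["\']([^"\':#]+)["\']', html):
            target = m.group(1)
            if target.startswith(("http", "mailto")):
                continue
            if not (page.parent / target).exists():
                broken.append(f"{page}: {target}")
    return broken
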