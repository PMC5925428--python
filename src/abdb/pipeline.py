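"""End-to-end processing: entries in, classified Fv datasets out.

For each entry the pipeline identifies chain types, decides the antibody
form, numbers the variable domains under all three schemes, reassembles
antibodies by contact (or by the L36/L87 rule for light dimers, regenerating
the partner from crystal symmetry when needed), assigns antigens with the
CDR-dominance rule, resolves anti-idiotype entries, and splits everything
into one file per antibody/antigen set.  Sets are then organised into the
3 forms x 4 complex classes x 3 schemes dataset taxonomy, with non-redundant
mirrors and redundancy/free-complexed lists.

Failures never abort a run: each entry either yields sets or a rejection
record, and re-running on identical input reproduces byte-identical output.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

from . import antigen_assign, assembly, chain_id, numbering, pdbio, redundancy
from .params import PipelineParams

log = logging.getLogger(__name__)

FORMS = ("complete", "light_only", "heavy_only")
CLASSES = ("free", "protein", "non_protein", "all")
SCHEMES = numbering.SCHEMES


@dataclass(frozen=True)
class DatasetKey:
    form: str
    complex_class: str
    scheme: str
    redundancy: str = "redundant"  # redundant | non_redundant

    def __post_init__(self):
        if self.form not in FORMS or self.complex_class not in CLASSES \
                or self.scheme not in SCHEMES:
            raise ValueError(f"invalid dataset key {self}")

    @property
    def relpath(self) -> str:
        prefix = "NR_" if self.redundancy == "non_redundant" else ""
        return os.path.join(f"{prefix}{self.form}", self.complex_class, self.scheme)


def all_dataset_keys(redundancy_level: str = "redundant") -> list:
    return [DatasetKey(f, c, s, redundancy_level)
            for f in FORMS for c in CLASSES for s in SCHEMES]


@dataclass
class RunReport:
    n_input_codes: int = 0
    n_processed: int = 0
    n_sets: int = 0
    per_form: dict = field(default_factory=lambda: {f: 0 for f in FORMS})
    per_class: dict = field(default_factory=lambda: {c: 0 for c in ("free", "protein", "non_protein")})
    rejections: dict = field(default_factory=dict)  # reason -> [codes]

    @property
    def n_rejected(self) -> int:
        return sum(len(v) for v in self.rejections.values())

    def check(self) -> None:
        assert self.n_input_codes == self.n_processed + self.n_rejected


@dataclass
class EntryResult:
    code: str
    sets: list = field(default_factory=list)           # AbAgSets with set ids
    rejection: str | None = None
    unassigned_chains: list = field(default_factory=list)
    rendered: dict = field(default_factory=dict)       # (set_id, scheme) -> pdb text
    chain_mappings: dict = field(default_factory=dict)  # set_id -> {out label: orig}
    labeled: dict = field(default_factory=dict)         # set_id -> LabeledSequence (martin)
    header: pdbio.HeaderMeta | None = None


class _WriteSet:
    """Duck-typed carrier handed to pdbio.write_fv_file."""

    def __init__(self, antibody_atoms, antigen_atoms):
        self.antibody_atoms = antibody_atoms
        self.antigen_atoms = antigen_atoms


def _number_all(model, chain, role, table):
    """Per-scheme NumberedChains for one chain; None on any failure."""
    source_chain = model.symmetry_copies.get(chain, (chain, None))[0]
    seq = model.seqres.get(source_chain, "")
    source = "seqres"
    if not seq:
        try:
            seq = pdbio.sequence_from_atoms(model, chain)
        except KeyError:
            return None
        source = "atom"
    out = {}
    for scheme in SCHEMES:
        nc = numbering.number_chain(seq, role, scheme, table)
        if nc is None:
            return None
        nc.source_chain_label = chain
        nc.source = source
        out[scheme] = nc
    return out


def _observed_labeled_sequence(atoms: list, role: str) -> dict:
    out = {}
    seen = set()
    for a in atoms:
        key = (a.res_seq, a.i_code)
        if key in seen:
            continue
        seen.add(key)
        out[f"{role}{a.res_seq}{a.i_code}"] = pdbio.three_to_one(a.res_name)
    return out


def process_entry(code: str, text: str,
                  params: PipelineParams | None = None,
                  profile=None, table=None) -> EntryResult:
    """Run the per-entry part of the pipeline (chain id through splitting)."""
    params = params or PipelineParams()
    profile = profile or chain_id.load_default_profile()
    table = table or numbering.load_scheme_table()
    result = EntryResult(code=code)
    try:
        model = pdbio.parse_pdb(text)
    except pdbio.EmptyStructureError as e:
        result.rejection = f"error: {e}"
        return result
    result.header = model.header

    calls = chain_id.assign_chain_types(model, profile, params.chain_score_threshold)
    form = chain_id.classify_form(calls, params.chain_score_threshold)
    if form.form == "rejected":
        result.rejection = form.reject_reason
        return result

    lights = [c.chain_label for c in calls if c.final == "light"]
    heavies = [c.chain_label for c in calls if c.final == "heavy"]
    candidates = [c.chain_label for c in calls if c.final == "antigen"]

    if form.form == "light_only" and len(lights) == 1:
        expanded = pdbio.expand_symmetry(model, chains=lights)
        if expanded is not model:
            model = expanded
            lights = lights + [lbl for lbl, (src, _t) in model.symmetry_copies.items()
                               if src in lights]

    # number every antibody chain under every scheme; any failure rejects the entry
    numbered: dict = {}
    for ch in lights:
        numbered[ch] = _number_all(model, ch, "L", table)
    for ch in heavies:
        numbered[ch] = _number_all(model, ch, "H", table)
    if any(v is None for v in numbered.values()):
        result.rejection = "numbering_failure"
        return result

    # Kabat-renumbered Fv atoms drive all geometry (contacts, dimer rule)
    try:
        fv_atoms = {ch: numbering.renumber_structure(
            model, ch, numbered[ch]["kabat"], "L" if ch in lights else "H")
            for ch in numbered}
    except numbering.NumberingFailure:
        result.rejection = "numbering_failure"
        return result

    # --- reassembly ---
    antibodies: list = []  # (chains [(new_label, orig, role)], )
    if form.form == "complete":
        try:
            pairs = assembly.pair_light_heavy(model, sorted(lights), sorted(heavies),
                                              params, atoms_by_chain=fv_atoms)
        except assembly.PairingError as e:
            result.rejection = f"error: {e}"
            return result
        paired = {c for p in pairs for c in p}
        result.unassigned_chains += [c for c in lights + heavies if c not in paired]
        for l, h in pairs:
            antibodies.append([("L", l, "L"), ("H", h, "H")])
    elif form.form == "light_only":
        pairs = assembly.pair_light_dimer(model, sorted(lights), params,
                                          atoms_by_chain=fv_atoms)
        paired = {c for p in pairs for c in p}
        for l1, l2 in pairs:
            antibodies.append([("L", l1, "L"), ("M", l2, "L")])
        for ch in sorted(lights):
            if ch not in paired:
                antibodies.append([("L", ch, "L")])
    else:
        for ch in sorted(heavies):
            antibodies.append([("H", ch, "H")])

    sets: list = []
    for chains in antibodies:
        ab_atoms = []
        chain_map, nmap = {}, {}
        for new_label, orig, role in chains:
            atoms = fv_atoms[orig]
            if new_label != ("L" if role == "L" else "H"):
                atoms = [replace(a, chain_label=new_label) for a in atoms]
            ab_atoms.extend(atoms)
            chain_map[new_label] = orig
            nmap[new_label] = numbered[orig]["kabat"]
        sets.append(assembly.AbAgSet(set_id="", entry_code=code, form=form.form,
                                     antibody_chain_map=chain_map, numbered=nmap,
                                     antibody_atoms=ab_atoms))

    # --- antigen assignment ---
    assigned_candidates: set = set()
    if candidates:
        for s in sets:
            profs = {c: antigen_assign.cdr_contact_profile(
                s, model.chain_atoms(c), c, params, table) for c in candidates}
            passing = [c for c in candidates
                       if profs[c].cdr_contacts > profs[c].framework_contacts
                       and profs[c].cdr_contacts >= params.min_cdr_contacts]
            contacting = [c for c in candidates if profs[c].cdr_contacts >= 1]
            antigen_set = list(passing)
            if params.multichain_combined and len(contacting) >= 2:
                cdr = sum(profs[c].cdr_contacts for c in contacting)
                fw = sum(profs[c].framework_contacts for c in contacting)
                if cdr > fw and cdr >= params.min_cdr_contacts:
                    antigen_set = sorted(set(passing) | set(contacting))
            s.binding_proteins = [c for c in candidates
                                  if profs[c].total > 0 and c not in antigen_set]
            if antigen_set:
                s.antigen_chains = sorted(antigen_set)
                s.antigen_atoms = [a for c in s.antigen_chains
                                   for a in model.chain_atoms(c)]
                s.antigen_kind = ("nucleic"
                                  if all(model.is_nucleic(c) for c in s.antigen_chains)
                                  else "protein")
                assigned_candidates.update(antigen_set)
        result.unassigned_chains += [c for c in candidates if c not in assigned_candidates
                                     and not any(c in s.binding_proteins for s in sets)]
    elif len(sets) >= 2:
        antigen_assign.resolve_anti_idiotype(sets, model, params, table)

    for s in sets:
        if s.antigen_kind != "none":
            continue
        serials = {a.serial for orig in s.antibody_chain_map.values()
                   for a in model.chain_atoms(orig)}
        for group in antigen_assign.collect_het_groups(model, serials):
            verdict = antigen_assign.classify_het_antigen(s, group, model, params, table)
            if verdict == "antigen":
                s.antigen_kind = "het"
                s.het_group = group
                s.antigen_atoms = s.antigen_atoms + sorted(group.atoms,
                                                           key=lambda a: a.serial)
                if group.group_id[1] not in s.antigen_chains:
                    s.antigen_chains = s.antigen_chains + [group.group_id[1]]

    for s in sets:
        antigen_assign.finalize_complex_class(s)

    sets = assembly.split_entry(code, sets)
    result.sets = sets

    # --- render per-scheme output ---
    for s in sets:
        out_ab_labels = set(s.antibody_chain_map)
        label_map = {}  # original antigen label -> written label
        written = set()
        for lbl in s.antigen_chains:
            out_lbl = lbl.lower() if lbl in out_ab_labels else lbl
            if out_lbl in written or out_lbl in out_ab_labels:
                result.rejection = "error: antigen chain label collision"
                result.sets = []
                result.rendered = {}
                return result
            written.add(out_lbl)
            label_map[lbl] = out_lbl
        ag_atoms = [replace(a, chain_label=label_map[a.chain_label])
                    if label_map.get(a.chain_label, a.chain_label) != a.chain_label
                    else a
                    for a in s.antigen_atoms]
        mapping = dict(s.antibody_chain_map)
        for orig, out_lbl in label_map.items():
            mapping[out_lbl] = orig
        for out_lbl in {a.chain_label for a in ag_atoms}:
            mapping.setdefault(out_lbl, out_lbl)
        result.chain_mappings[s.set_id] = mapping

        roles = s.roles
        for scheme in SCHEMES:
            ab_atoms = []
            for new_label in sorted(s.antibody_chain_map):
                orig = s.antibody_chain_map[new_label]
                ab_atoms.extend(numbering.renumber_structure(
                    model, orig, numbered[orig][scheme], new_label))
            result.rendered[(s.set_id, scheme)] = pdbio.write_fv_file(
                _WriteSet(ab_atoms, ag_atoms), scheme, model.header, mapping)
            if scheme == "martin":
                chains = {}
                if s.form == "complete":
                    wanted = {"L": "L", "H": "H"}
                elif s.form == "light_only":
                    wanted = {"L": "L"}
                else:
                    wanted = {"H": "H"}
                for new_label, role in wanted.items():
                    chain_atoms = [a for a in ab_atoms if a.chain_label == new_label]
                    chains[role] = _observed_labeled_sequence(chain_atoms, role)
                result.labeled[s.set_id] = redundancy.LabeledSequence.from_dict(
                    s.form, chains)
    return result


def _read_entry_file(pdb_dir: str, code: str) -> str | None:
    for name in (f"{code.lower()}.pdb", f"{code.upper()}.pdb", f"pdb{code.lower()}.ent",
                 f"{code.lower()}.ent"):
        path = os.path.join(pdb_dir, name)
        if os.path.exists(path):
            with open(path) as fh:
                return fh.read()
    return None


def run_pipeline(codes: list, pdb_dir: str,
                 params: PipelineParams | None = None,
                 out_dir: str = "abdb_out",
                 schemes: tuple = SCHEMES) -> RunReport:
    """Process an entry list and lay out the full dataset taxonomy."""
    params = params or PipelineParams()
    report = RunReport(n_input_codes=len(codes))
    results: list = []
    for code in codes:
        text = _read_entry_file(pdb_dir, code)
        if text is None:
            report.rejections.setdefault("missing", []).append(code)
            continue
        try:
            res = process_entry(code, text, params)
        except Exception as e:  # never abort the run
            log.exception("entry %s failed", code)
            report.rejections.setdefault("error", []).append(code)
            continue
        if res.rejection is not None:
            reason = res.rejection.split(":")[0]
            report.rejections.setdefault(reason, []).append(code)
            continue
        report.n_processed += 1
        results.append(res)

    all_sets = [s for r in results for s in r.sets]
    labeled = {s.set_id: r.labeled[s.set_id] for r in results for s in r.sets}
    rendered = {k: v for r in results for k, v in r.rendered.items()}
    meta = {}
    for r in results:
        for s in r.sets:
            meta[s.set_id] = (labeled[s.set_id].length,
                              r.header.resolution if r.header else None)
    status = {s.set_id: s.complex_class for s in all_sets}
    report.n_sets = len(all_sets)
    for s in all_sets:
        report.per_form[s.form] += 1
        report.per_class[s.complex_class] += 1
    report.check()

    # --- redundancy per (form, class) ---
    clusters_by: dict = {}
    for form in FORMS:
        for cls in CLASSES:
            members = {s.set_id: labeled[s.set_id] for s in all_sets
                       if s.form == form
                       and (cls == "all" or s.complex_class == cls)}
            cl = redundancy.cluster(members)
            for c in cl:
                redundancy.select_representative(c, meta)
            clusters_by[(form, cls)] = cl

    # --- write datasets ---
    by_set = {s.set_id: s for s in all_sets}
    for form in FORMS:
        for cls in CLASSES:
            cl = clusters_by[(form, cls)]
            members = sorted(m for c in cl for m in c.members)
            reps = sorted(c.representative for c in cl)
            for scheme in schemes:
                for level, ids in (("redundant", members), ("non_redundant", reps)):
                    key = DatasetKey(form, cls, scheme, level)
                    if not ids:
                        continue
                    ddir = os.path.join(out_dir, key.relpath)
                    os.makedirs(ddir, exist_ok=True)
                    for set_id in ids:
                        with open(os.path.join(ddir, f"{set_id}.pdb"), "w") as fh:
                            fh.write(rendered[(set_id, scheme)])

    # --- lists ---
    if all_sets:
        ldir = os.path.join(out_dir, "lists")
        os.makedirs(ldir, exist_ok=True)
        for form in FORMS:
            for cls in CLASSES:
                with open(os.path.join(ldir, f"redundancy_{form}_{cls}.tsv"), "w") as fh:
                    fh.write(redundancy.emit_redundancy_list(clusters_by[(form, cls)]))
            rows = redundancy.free_complexed_pairs(clusters_by[(form, "all")], status)
            with open(os.path.join(ldir, f"free_complexed_{form}.tsv"), "w") as fh:
                fh.write(redundancy.emit_free_complexed_list(rows))
        with open(os.path.join(ldir, "chain_mapping.tsv"), "w") as fh:
            fh.write("#set_id\tmapping\n")
            for r in results:
                for set_id in sorted(r.chain_mappings):
                    mp = r.chain_mappings[set_id]
                    pairs = ",".join(f"{k}:{v}" for k, v in sorted(mp.items()))
                    fh.write(f"{set_id}\t{pairs}\n")

        # flat manifest used by `abdb query`
        cluster_of = {}
        for form in FORMS:
            for ordinal, c in enumerate(clusters_by[(form, "all")], start=1):
                for m in c.members:
                    cluster_of[m] = (form, ordinal, m == c.representative)
        with open(os.path.join(out_dir, "index.tsv"), "w") as fh:
            fh.write("#set_id\tform\tclass\tresolution\trfactor\tabname\tabspecies"
                     "\tagname\tagspecies\tcluster\trepresentative\n")
            for set_id in sorted(by_set):
                s = by_set[set_id]
                r = next(r for r in results if any(x.set_id == set_id for x in r.sets))
                h = r.header or pdbio.HeaderMeta()
                origs = [s.antibody_chain_map[k] for k in sorted(s.antibody_chain_map)]
                abname = next((h.molecule_names.get(c, "") for c in origs
                               if h.molecule_names.get(c)), "")
                abspec = next((h.species.get(c, "") for c in origs
                               if h.species.get(c)), "")
                agname = next((h.molecule_names.get(c, "") for c in s.antigen_chains
                               if h.molecule_names.get(c)), "")
                agspec = next((h.species.get(c, "") for c in s.antigen_chains
                               if h.species.get(c)), "")
                _form, ordinal, rep = cluster_of[set_id]
                fh.write("\t".join([
                    set_id, s.form, s.complex_class,
                    f"{h.resolution:.2f}" if h.resolution is not None else "",
                    f"{h.r_factor:.3f}" if h.r_factor is not None else "",
                    abname, abspec, agname, agspec,
                    str(ordinal), "1" if rep else "0"]) + "\n")
    return report


def query(out_dir: str, by: str, term: str) -> list:
    """Search the built index by code, keyword or species.

    Matching sets are returned together with every set redundant with them
    (same cluster in the per-form all-classes clustering).  Each row is a
    dict of the index columns.
    """
    index_path = os.path.join(out_dir, "index.tsv")
    if not os.path.exists(index_path):
        return []
    rows = []
    with open(index_path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    term_l = term.lower()
    if by == "code":
        hits = [r for r in rows if r["set_id"].lower() == term_l
                or r["set_id"].lower().startswith(term_l + "_")]
    elif by == "keyword":
        hits = [r for r in rows
                if term_l in r["abname"].lower() or term_l in r["agname"].lower()]
    elif by == "species":
        hits = [r for r in rows
                if term_l in r["abspecies"].lower() or term_l in r["agspecies"].lower()]
    else:
        raise ValueError("by must be code, keyword or species")
    clusters = {(r["form"], r["cluster"]) for r in hits}
    out = [r for r in rows if (r["form"], r["cluster"]) in clusters]
    return sorted(out, key=lambda r: r["set_id"])
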