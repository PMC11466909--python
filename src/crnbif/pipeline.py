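"""Census orchestration: enumerate, filter, classify, and report.

Every summary counter is keyed by the statement it reproduces (e.g.
``"Lemma21.total"``), so the aggregate results of the whole classification can
be checked as named integers.  The pipeline is fully deterministic - there is
no randomness anywhere in exact mode - and regenerating a report yields
byte-identical files.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from . import tables
from .bt import bt_normal_form
from .core import Network
from .enumeration import (census, network_equivalence_key,
                          spec_bimolecular_distinct, spec_hopf_base,
                          spec_trimolecular_distinct)
from .equilibria import (admits_nondegenerate_equilibrium, diag_signs_at_roots,
                         purely_imaginary_feasible, second_eigenvalue_signs,
                         zero_eigenvalue_feasible)
from .equivalence import count_diagonal_classes
from .fold import classify_fold, origin_stability, vertical_fold
from .hopf import classify_hopf


@dataclass
class CensusReport:
    counters: dict = field(default_factory=dict)
    rows: dict = field(default_factory=dict)     # track -> list of per-network dicts
    networks: dict = field(default_factory=dict) # label -> list of Networks


def _fold_partition(nets):
    nondeg = [n for n in nets if admits_nondegenerate_equilibrium(n)]
    zero = [n for n in nondeg if zero_eigenvalue_feasible(n)[0]]
    forced, fold = [], []
    for n in zero:
        if any((s11, s22) != (0, 0) for _, s11, s22 in diag_signs_at_roots(n)):
            fold.append(n)
        else:
            forced.append(n)
    return nondeg, zero, forced, fold


def run_census(tracks=("fold", "bimolecular", "hopf", "bt"),
               verify_fold_witnesses: bool = False) -> CensusReport:
    """Run the selected classification tracks and collect named counters.

    ``verify_fold_witnesses`` additionally certifies a nondegenerate-fold
    witness (quadratic coefficient + transversality) for each fold network.
    """
    rep = CensusReport()
    c = rep.counters
    need_fold = {"fold", "bt"} & set(tracks)
    need_hopf = {"hopf", "bt"} & set(tracks)

    if need_fold:
        nets = census(spec_trimolecular_distinct())
        nondeg, zero, forced, fold = _fold_partition(nets)
        rep.networks["trimolecular"] = nets
        rep.networks["fold"] = fold
        rep.networks["forced_double_zero"] = forced
        if "fold" in tracks:
            c["Lemma21.total"] = len(nets)
            c["Lemma21.nondegenerate"] = len(nondeg)
            c["Theorem22.zero_eigenvalue"] = len(zero)
            c["Theorem22.forced_double_zero"] = len(forced)
            c["Theorem22.fold"] = len(fold)
            signs = {n: second_eigenvalue_signs(n) for n in fold}
            c["Theorem22.second_negative"] = sum(
                1 for n in fold if "negative" in signs[n])
            c["Theorem22.second_positive"] = sum(
                1 for n in fold if "positive" in signs[n])
            c["Theorem22.second_both"] = sum(
                1 for n in fold if signs[n] == {"negative", "positive"})
            c["Remark23a.diagonal_classes"] = count_diagonal_classes(fold)
            degen = [n for n in nets if not admits_nondegenerate_equilibrium(n)]
            c["Remark23f.vertical_fold"] = len(degen)
            rows = []
            for n in fold:
                row = {"network": n.serialise(),
                       "second_eigenvalue": sorted(signs[n])}
                if verify_fold_witnesses:
                    row["fold_nondegenerate"] = classify_fold(n).fold_nondegenerate
                rows.append(row)
            for n in degen:
                rows.append({"network": n.serialise(),
                             "vertical_fold_line": vertical_fold(n)})
            rep.rows["fold"] = rows

    if "bimolecular" in tracks:
        bnets = census(spec_bimolecular_distinct())
        bnondeg, bzero, bforced, bfold = _fold_partition(bnets)
        c["Lemma24.total"] = len(bnets)
        c["Lemma24.nondegenerate"] = len(bnondeg)
        c["Theorem25.fold"] = len(bzero)
        stab = {n: origin_stability(n) for n in bzero}
        c["Lemma27.bistable"] = sum(
            1 for n in bzero
            if stab[n] in ("linearly-stable", "stable-via-center-manifold"))
        rep.networks["bimolecular_fold"] = bzero
        rep.rows["bimolecular"] = [
            {"network": n.serialise(), "origin": stab[n]} for n in bzero]

    if need_hopf:
        base = census(spec_hopf_base())
        hopf = [n for n in base if purely_imaginary_feasible(n)]
        rep.networks["hopf_base"] = base
        rep.networks["hopf"] = hopf
        if "hopf" in tracks:
            c["Lemma28.base"] = len(base)
            c["Lemma29.hopf"] = len(hopf)
            rows = []
            kinds = {}
            for n in hopf:
                cls = classify_hopf(n)
                kinds[n] = cls
                rows.append({"network": n.serialise(), "hopf_type": cls.kind,
                             "transversal": cls.transversal})
            for kind in ("supercritical", "subcritical", "vertical", "mixed",
                         "bautin"):
                c[f"Theorem30.{kind}"] = sum(
                    1 for v in kinds.values() if v.kind == kind)
            c["Remark31a.diagonal_classes"] = count_diagonal_classes(hopf)
            rep.rows["hopf"] = rows

    if "bt" in tracks:
        fold_keys = {network_equivalence_key(n) for n in rep.networks["fold"]}
        hopf_keys = {network_equivalence_key(n) for n in rep.networks["hopf"]}
        common = fold_keys & hopf_keys
        cand = [n for n in rep.networks["fold"]
                if network_equivalence_key(n) in common]
        c["Lemma32.fold_and_hopf"] = len(common)
        records = [(n, bt_normal_form(n)) for n in cand]
        btnets = [(n, r) for n, r in records if r.double_zero_feasible]
        c["Lemma32.double_zero"] = len(btnets)
        c["Theorem33.supercritical"] = sum(1 for _, r in btnets if r.sigma == -1)
        c["Theorem33.vertical"] = sum(1 for _, r in btnets if r.vertical_bt)
        c["Theorem33.subcritical"] = sum(1 for _, r in btnets if r.sigma == +1)
        c["Remark34a.diagonal_classes"] = count_diagonal_classes(
            [n for n, _ in btnets])
        rep.networks["bt"] = [n for n, _ in btnets]
        rep.rows["bt"] = [
            {"network": n.serialise(),
             "sigma": r.sigma if r.sigma is not None else "vertical",
             "transversal": r.transversal}
            for n, r in btnets]
    return rep


def verify_against_table3(report: CensusReport | None = None):
    """Check the computed BT catalog against the printed 33-network table.

    Compares the sets of dynamical-equivalence classes and the printed
    supercritical / vertical / subcritical split; returns
    ``(ok, mismatches)``.
    """
    if report is None or "bt" not in report.rows:
        report = run_census(tracks=("fold", "hopf", "bt"))
    printed = tables.table3_networks()
    printed_keys = {network_equivalence_key(n): i + 1
                    for i, n in enumerate(printed)}
    computed = {network_equivalence_key(n): row
                for n, row in zip(report.networks["bt"], report.rows["bt"])}
    mismatches = []
    if set(printed_keys) != set(computed):
        missing = [tables.TABLE3[i - 1] for k, i in printed_keys.items()
                   if k not in computed]
        extra = [computed[k]["network"] for k in computed
                 if k not in printed_keys]
        mismatches.append({"missing": missing, "extra": extra})
        return False, mismatches
    for key, rownum in printed_keys.items():
        sigma = computed[key]["sigma"]
        want = (-1 if rownum in tables.TABLE3_SUPERCRITICAL else
                "vertical" if rownum in tables.TABLE3_VERTICAL else +1)
        if sigma != want:
            mismatches.append({"row": rownum, "computed": sigma, "printed": want})
    return not mismatches, mismatches


def emit_reports(report: CensusReport, out_dir) -> list[str]:
    """Write deterministic CSV/JSON/Markdown artifacts; returns file paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "counters.json"
    path.write_text(json.dumps(dict(sorted(report.counters.items())), indent=1)
                    + "\n")
    written.append(str(path))

    for track, rows in sorted(report.rows.items()):
        path = out / f"{track}.csv"
        buf = io.StringIO()
        cols = sorted({k for row in rows for k in row})
        w = csv.DictWriter(buf, fieldnames=cols)
        w.writeheader()
        for row in sorted(rows, key=lambda r: r["network"]):
            w.writerow({k: row.get(k, "") for k in cols})
        path.write_text(buf.getvalue())
        written.append(str(path))

    md = ["# Census summary", ""]
    for key, val in sorted(report.counters.items()):
        md.append(f"- {key}: {val}")
    path = out / "summary.md"
    path.write_text("\n".join(md) + "\n")
    written.append(str(path))
    return written
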