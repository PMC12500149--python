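"""Result artifacts: dominant-mode tables and equilibria graphs.

For each period the dominant active mode (mode M+1) is characterised at
the period's representative time by its CSP Pointer (which species the
mode is attached to) and its timescale participation index (which
reactions generate its timescale, signed dissipative/explosive).  The
exhausted modes r <= M define the period's established equilibria:
reactions are classified by their amplitude participation, species by
pointer entries, mirroring the published filtering conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .csp import (amplitude_participation_index, csp_pointer,
                  timescale_participation_index)
from .registry import LABELS
from .segmentation import CSPConfig, Period, decompose_at
from .simulate import Trajectory
from .state import STATE_NAMES

#: Published filtering conventions.
TPI_FILTER = 0.03        # report |TPI| >= 3 %
PO_FILTER = 0.03         # report pointer entries >= 0.03
API_STRONG = 0.09        # strong equilibrium participation, |API| > 9 %
API_WEAK = 0.02          # weak participation, 2 % <= |API| <= 9 %
PO_QSS = 0.45            # species pointer threshold for the graphs


@dataclass
class DominantModeReport:
    period: str
    representative_time: float
    mode: int                          # 1-based dominant active mode (M+1)
    timescale: float                   # s
    species: list[tuple[str, float]]   # (name, Po), |Po| >= PO_FILTER, desc
    reactions: list[tuple[str, float]]  # (label, TPI %), |TPI| >= 3 %, desc
    character: str                     # "dissipative" | "explosive"
    tpi_sum: float                     # sum of all signed TPIs (percent)
    po_filter: float = PO_FILTER
    tpi_filter: float = TPI_FILTER


@dataclass
class EquilibriaGraph:
    period: str
    representative_time: float
    n_exhausted: int
    strong: dict[str, int] = field(default_factory=dict)   # label -> mode (1-based)
    weak: dict[str, int] = field(default_factory=dict)
    species: dict[str, int] = field(default_factory=dict)  # name -> mode
    api_strong: float = API_STRONG
    api_weak: float = API_WEAK
    po_threshold: float = PO_QSS


def dominant_mode_report(period: Period, traj: Trajectory,
                         config: CSPConfig | None = None) -> DominantModeReport:
    """Pointer and TPI table of the dominant active mode of a period."""
    t = period.representative_time
    if not period.t_start <= t <= period.t_end:
        raise ValueError(f"representative time {t} outside period "
                         f"[{period.t_start}, {period.t_end}]")
    y, decomp = decompose_at(traj, t)
    model = traj.model
    mode = period.M            # 0-based index of mode M+1
    po = csp_pointer(decomp, mode)
    grads = model.rate_gradients(y, t)
    tpi = 100.0 * timescale_participation_index(decomp, model.S, grads, mode)

    sp = [(STATE_NAMES[i], float(po[i])) for i in np.argsort(-np.abs(po))
          if abs(po[i]) >= PO_FILTER]
    rx = [(LABELS[k], float(tpi[k])) for k in np.argsort(-np.abs(tpi))
          if abs(tpi[k]) >= 100.0 * TPI_FILTER]
    s = float(np.sum(tpi))
    return DominantModeReport(
        period=period.label, representative_time=t, mode=period.dominant_mode,
        timescale=float(decomp.timescales[mode]), species=sp, reactions=rx,
        character="dissipative" if s < 0 else "explosive", tpi_sum=s)


def equilibria_graph(period: Period, traj: Trajectory,
                     config: CSPConfig | None = None) -> EquilibriaGraph:
    """Reactions and species participating in the period's equilibria.

    For every exhausted mode r <= M at the representative time, reactions
    are classed by their largest |API| over modes (strong > 9 %, weak
    2-9 %) and species are listed when any exhausted-mode pointer entry
    exceeds 45 %.  The contributing mode is retained as provenance.
    """
    import warnings

    t = period.representative_time
    y, decomp = decompose_at(traj, t)
    model = traj.model
    g = EquilibriaGraph(period=period.label, representative_time=t,
                        n_exhausted=period.M)
    if period.M == 0:
        warnings.warn(f"period {period.label} has no exhausted modes; "
                      "empty equilibria graph")
        return g
    R = model.rates(y, t)
    best_api: dict[str, tuple[float, int]] = {}
    for r in range(period.M):
        try:
            api = amplitude_participation_index(decomp, model.S, R, r)
        except ZeroDivisionError:
            # a mode whose projected rates all vanish (e.g. the venous
            # volume mode at plateau) has an undefined API; its pointer
            # is still informative
            api = np.zeros(model.S.shape[1])
        for k, lab in enumerate(LABELS):
            a = abs(api[k])
            if a >= API_WEAK and a > best_api.get(lab, (0.0, 0))[0]:
                best_api[lab] = (a, r + 1)
        po = csp_pointer(decomp, r)
        for i, name in enumerate(STATE_NAMES):
            if po[i] > PO_QSS and name not in g.species:
                g.species[name] = r + 1
    for lab, (a, mode) in sorted(best_api.items()):
        (g.strong if a > API_STRONG else g.weak)[lab] = mode
    return g


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _report_frame(rep: DominantModeReport):
    import pandas as pd
    n = max(len(rep.species), len(rep.reactions), 1)
    rows = []
    for i in range(n):
        rows.append({
            "period": rep.period,
            "representative_time_s": rep.representative_time,
            "mode": rep.mode,
            "species": rep.species[i][0] if i < len(rep.species) else "",
            "Po": rep.species[i][1] if i < len(rep.species) else np.nan,
            "reaction": rep.reactions[i][0] if i < len(rep.reactions) else "",
            "TPI_percent": rep.reactions[i][1] if i < len(rep.reactions) else np.nan,
            "character": rep.character,
        })
    return pd.DataFrame(rows)


def write_outputs(reports: list[DominantModeReport],
                  graphs: list[EquilibriaGraph],
                  out_dir: str | Path,
                  manifest_extra: dict | None = None) -> list[Path]:
    """Write dominant-mode CSV tables, equilibria graphs and a manifest.

    Output is deterministic (byte-stable) for fixed inputs.  Returns the
    written paths; an empty report set produces only the manifest.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []

    if reports:
        import pandas as pd
        df = pd.concat([_report_frame(r) for r in reports], ignore_index=True)
        path = out_dir / "dominant_modes.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        path = out_dir / "dominant_modes.json"
        payload = [{"period": r.period, "t": r.representative_time,
                    "mode": r.mode, "timescale_s": r.timescale,
                    "species": r.species, "reactions": r.reactions,
                    "character": r.character, "tpi_sum": r.tpi_sum,
                    "filters": {"Po": r.po_filter, "TPI": r.tpi_filter}}
                   for r in reports]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)

    if graphs:
        nodes, edges = [], []
        for gph in graphs:
            for name, mode in sorted(gph.species.items()):
                nodes.append({"period": gph.period, "species": name,
                              "mode": mode})
            for cls, d in (("strong", gph.strong), ("weak", gph.weak)):
                for lab, mode in sorted(d.items()):
                    edges.append({"period": gph.period, "reaction": lab,
                                  "class": cls, "mode": mode})
        import pandas as pd
        for fname, recs in (("equilibria_species.csv", nodes),
                            ("equilibria_reactions.csv", edges)):
            path = out_dir / fname
            pd.DataFrame(recs).to_csv(path, index=False)
            written.append(path)
        path = out_dir / "equilibria.json"
        payload = [{"period": gph.period, "t": gph.representative_time,
                    "M": gph.n_exhausted, "strong": gph.strong,
                    "weak": gph.weak, "species": gph.species,
                    "thresholds": {"strong": gph.api_strong,
                                   "weak": gph.api_weak,
                                   "Po": gph.po_threshold}}
                   for gph in graphs]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)

    manifest = {"n_reports": len(reports), "n_graphs": len(graphs),
                "files": sorted(p.name for p in written)}
    manifest.update(manifest_extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(path)
    return written
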