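"""Automated setup of the pocket-shape metadynamics protocol.

Given an apo structure, a binding-site residue list and a quasi-rigid
domain map, this module builds the full collective-variable set (site
gyration radius, three contacts-across-inertia-plane CVs, one
contacts-between-domains CV per mobile/core interface, optionally split
into charged/uncharged sub-CVs), estimates Gaussian hill widths from a
short unbiased CV series, lays out the gyration-radius restraint
schedule that steers the pocket toward a contracted (holo-like) state,
and emits a deterministic PLUMED-dialect input deck.

Defaults follow well-tempered bias-exchange metadynamics practice for
pocket sampling: hills of 0.6 kcal/mol deposited every 2.5 ps, bias
factor 10, replica exchanges every 50 ps, an upper gyration-radius wall
whose force constant ramps 10 -> 25 kcal/mol/Å² and whose center then
descends stepwise (1 ns steps) to 85% of the apo value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .cvs import (
    CVDefinition,
    CVSeries,
    SwitchingParams,
    partition_residues_across_plane,
    principal_inertia_frame,
    radius_of_gyration,
)
from .structures import (
    DEFAULT_CHARGED_RESIDUES,
    DomainMap,
    SiteDefinition,
    Structure,
    classify_residue_charge,
    residue_sort_key,
)

__all__ = [
    "MetaDParams",
    "RestraintPhase",
    "RestraintSchedule",
    "ProtocolBundle",
    "build_binding_site_cvs",
    "select_interface_residues",
    "build_crd_cvs",
    "apply_charged_split",
    "estimate_hill_widths",
    "build_restraint_schedule",
    "build_protocol",
    "emit_metadynamics_input",
    "parse_metadynamics_input",
    "render_deck",
]


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics parameters (energies kcal/mol, times ps)."""

    hill_height: float = 0.6
    bias_factor: float = 10.0
    deposition_ps: float = 2.5
    exchange_ps: float = 50.0
    widths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, what in ((self.hill_height, "hill height"),
                        (self.bias_factor, "bias factor"),
                        (self.deposition_ps, "deposition period"),
                        (self.exchange_ps, "exchange period")):
            if v <= 0:
                raise ValueError(f"{what} must be positive")
        if any(w <= 0 for w in self.widths.values()):
            raise ValueError("hill widths must be positive")


@dataclass(frozen=True)
class RestraintPhase:
    duration_ns: float
    wall: str                 # "none" | "upper"
    k_start: float            # kcal/mol/Å²
    k_end: float
    center_start: float | None  # Å; None when wall == "none"
    center_end: float | None
    stepwise_ns: float | None = None  # discretize center updates, e.g. 1 ns

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError("phase duration must be positive")
        if self.wall not in ("none", "upper"):
            raise ValueError(f"unknown wall type {self.wall!r}")


@dataclass(frozen=True)
class RestraintSchedule:
    """Piecewise-linear upper wall on the site gyration radius."""

    phases: tuple[RestraintPhase, ...]
    rog_apo: float
    target_fraction: float = 0.85

    @property
    def total_ns(self) -> float:
        return sum(p.duration_ns for p in self.phases)

    def _locate(self, t_ns: float) -> tuple[RestraintPhase, float]:
        if t_ns < 0:
            raise ValueError("negative time")
        start = 0.0
        for phase in self.phases:
            if t_ns <= start + phase.duration_ns:
                return phase, t_ns - start
            start += phase.duration_ns
        return self.phases[-1], self.phases[-1].duration_ns

    def k_at(self, t_ns: float) -> float:
        phase, elapsed = self._locate(t_ns)
        if phase.wall == "none":
            return 0.0
        return phase.k_start + (phase.k_end - phase.k_start) * elapsed / phase.duration_ns

    def center_at(self, t_ns: float) -> float | None:
        phase, elapsed = self._locate(t_ns)
        if phase.wall == "none":
            return None
        if phase.center_start == phase.center_end:
            return phase.center_start
        frac = elapsed / phase.duration_ns
        if phase.stepwise_ns:
            frac = np.floor(elapsed / phase.stepwise_ns) * phase.stepwise_ns / phase.duration_ns
            frac = min(frac, 1.0)
        return phase.center_start + (phase.center_end - phase.center_start) * frac


def build_restraint_schedule(rog_apo: float,
                             durations_ns=(10.0, 40.0, 400.0, 150.0),
                             k_range=(10.0, 25.0),
                             target_fraction: float = 0.85,
                             step_ns: float = 1.0) -> RestraintSchedule:
    """Four-phase gyration-radius restraint schedule.

    1. unrestrained equilibration;
    2. upper wall at the apo value, force constant ramping k_lo -> k_hi;
    3. wall center descending (stepwise every ``step_ns``) to
       ``target_fraction`` x apo at constant k_hi;
    4. hold at the target.
    """
    if rog_apo <= 0:
        raise ValueError("apo gyration radius must be positive")
    if not (0 < target_fraction <= 1):
        raise ValueError("target fraction must be in (0, 1]")
    if len(durations_ns) != 4 or any(d <= 0 for d in durations_ns):
        raise ValueError("need four positive phase durations")
    k_lo, k_hi = k_range
    target = target_fraction * rog_apo
    phases = (
        RestraintPhase(durations_ns[0], "none", 0.0, 0.0, None, None),
        RestraintPhase(durations_ns[1], "upper", k_lo, k_hi, rog_apo, rog_apo),
        RestraintPhase(durations_ns[2], "upper", k_hi, k_hi, rog_apo, target,
                       stepwise_ns=step_ns),
        RestraintPhase(durations_ns[3], "upper", k_hi, k_hi, target, target),
    )
    return RestraintSchedule(phases=phases, rog_apo=rog_apo,
                             target_fraction=target_fraction)


# ------------------------------------------------------------- CV building

def build_binding_site_cvs(structure: Structure, site: SiteDefinition,
                           switching: SwitchingParams | None = None,
                           rog_mass_weighted: bool = True):
    """Build the site gyration CV and the three inertia-plane contact CVs.

    Returns ``(rog_cv, [cip_1, cip_2, cip_3], inertia_frame, audit)``.
    The inertia frame is computed once on the (apo) input structure and
    frozen into the CV atom groups; it is not recomputed per frame.
    """
    site.validate(structure)
    if len(site) < 3:
        raise ValueError("binding site must contain at least 3 residues")
    bb = structure.backbone_indices(site.residues)
    if len(bb) < 3:
        raise ValueError("site has fewer than 3 backbone atoms")
    heavy = structure.heavy_indices(site.residues)
    frame = principal_inertia_frame(structure.coords[heavy], structure.masses[heavy])
    audit = [
        f"site: {len(site)} residues, {len(heavy)} heavy atoms, "
        f"{len(bb)} backbone atoms",
        "inertia moments (ascending): "
        + ", ".join(f"{m:.4g}" for m in frame.moments),
    ]
    rog_cv = CVDefinition(
        name="rog_bs", kind="ROG", group_a=bb,
        weights=structure.masses[bb] if rog_mass_weighted else np.ones(len(bb)),
        residues_a=tuple(site.residues),
    )
    switching = switching or SwitchingParams()
    cips = []
    for k in range(3):
        group_a, group_b = partition_residues_across_plane(
            structure, site, frame.axes[k], frame.center
        )
        audit.append(
            f"cip_{k + 1}: plane normal ({', '.join(f'{c:.4f}' for c in frame.axes[k])}), "
            f"split {len(group_a)}/{len(group_b)} residues"
        )
        cips.append(
            CVDefinition(
                name=f"cip_{k + 1}", kind="CIP",
                group_a=structure.heavy_indices(group_a),
                group_b=structure.heavy_indices(group_b) if group_b
                else np.array([], dtype=int),
                switching=switching,
                residues_a=tuple(group_a), residues_b=tuple(group_b),
            )
        )
    return rog_cv, cips, frame, audit


def select_interface_residues(structure: Structure, site: SiteDefinition,
                              domains: DomainMap, mobile_label: str,
                              core_label: str, cutoff: float = 8.0) -> list[str]:
    """Site residues lining a mobile/core domain interface.

    Union of (i) site residues of the mobile domain within ``cutoff`` Å
    (minimum heavy-atom distance) of *any* residue of the core domain,
    and (ii) the specular selection of site residues of the core domain
    near the mobile one.
    """
    for lab in (mobile_label, core_label):
        if lab not in domains.labels:
            raise KeyError(f"domain label {lab!r} not in domain map")

    def domain_coords(label):
        res = [r for r in domains.residues_of(label) if structure.has_residue(r)]
        idx = structure.heavy_indices(res)
        return structure.coords[idx]

    mobile_xyz = domain_coords(mobile_label)
    core_xyz = domain_coords(core_label)
    selected = []
    for rid in site:
        lab = domains.domain_of(rid)
        if lab == mobile_label:
            other = core_xyz
        elif lab == core_label:
            other = mobile_xyz
        else:
            continue
        mine = structure.coords[structure.heavy_indices([rid])]
        if len(mine) and len(other):
            d = np.linalg.norm(mine[:, None, :] - other[None], axis=-1).min()
            if d <= cutoff:
                selected.append(rid)
    if not selected:
        raise ValueError(
            f"no {mobile_label}/{core_label} interface residues within "
            f"{cutoff} Å; consider a larger cutoff"
        )
    return selected


def build_crd_cvs(structure: Structure, site: SiteDefinition, domains: DomainMap,
                  core_label: str = "CORE", cutoff: float = 8.0,
                  switching: SwitchingParams | None = None,
                  min_residues_per_side: int = 4):
    """One inter-domain contact CV per mobile/core interface of the site.

    Validity checks: (a) no site residue may belong to more than one
    interface CV (reduce the cutoff if this fails); (b) each domain side
    of each interface must contribute at least ``min_residues_per_side``
    residues, limiting the risk of distorting secondary structure when
    the contacts are biased.
    """
    site.validate(structure)
    if core_label not in domains.labels:
        raise KeyError(f"core domain {core_label!r} not in domain map")
    mobile_labels = [lab for lab in domains.labels if lab != core_label]
    switching = switching or SwitchingParams()
    audit: list[str] = []
    if not mobile_labels:
        warnings.warn("single-domain map: no inter-domain CVs defined")
        return [], audit

    cvs: list[CVDefinition] = []
    assigned: dict[str, str] = {}
    for mobile in mobile_labels:
        try:
            interface = select_interface_residues(
                structure, site, domains, mobile, core_label, cutoff
            )
        except ValueError:
            audit.append(f"crd: no {mobile}/{core_label} interface within "
                         f"{cutoff} Å; skipped")
            continue
        for rid in interface:
            if rid in assigned:
                raise ValueError(
                    f"residue {rid} assigned to both the {assigned[rid]} and "
                    f"{mobile} interfaces; reduce the interface cutoff "
                    f"(currently {cutoff} Å)"
                )
            assigned[rid] = mobile
        side_mobile = [r for r in interface if domains.domain_of(r) == mobile]
        side_core = [r for r in interface if domains.domain_of(r) == core_label]
        for side, lab in ((side_mobile, mobile), (side_core, core_label)):
            if len(side) < min_residues_per_side:
                raise ValueError(
                    f"{mobile}/{core_label} interface has only {len(side)} "
                    f"residues on the {lab} side (minimum "
                    f"{min_residues_per_side}); adjust the cutoff"
                )
        name = f"crd_{mobile.lower()}"
        audit.append(
            f"{name}: {len(side_mobile)} {mobile} residues vs "
            f"{len(side_core)} {core_label} residues (cutoff {cutoff} Å)"
        )
        cvs.append(
            CVDefinition(
                name=name, kind="CRD",
                group_a=structure.heavy_indices(side_mobile),
                group_b=structure.heavy_indices(side_core),
                switching=switching,
                residues_a=tuple(side_mobile), residues_b=tuple(side_core),
            )
        )
    return cvs, audit


def _has_nonadjacent_pair(residues) -> bool:
    """True if some pair of residues is non-adjacent in sequence.

    Adjacent = same chain and residue numbers differing by < 2.
    """
    keys = [residue_sort_key(r) for r in residues]
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if keys[i][0] != keys[j][0] or abs(keys[i][1] - keys[j][1]) >= 2:
                return True
    return False


def apply_charged_split(structure: Structure, crd_cv: CVDefinition,
                        charged_residues, site_charged_fraction: float,
                        fraction_threshold: float = 0.25):
    """Split an inter-domain contact CV into charged/uncharged sub-CVs.

    The split is applied only when (i) the site's charged fraction
    exceeds ``fraction_threshold`` and (ii) every resulting residue
    group (charged and uncharged, on both domain sides) contains at
    least 2 non-adjacent residues.  Charged side chains face lower
    free-energy barriers for small rearrangements than bulky apolar
    ones, so biasing their contacts separately keeps them from being
    dragged along with the rest of the interface.

    Returns ``(cvs, decision)`` where ``cvs`` is either ``[crd_cv]``
    unchanged or the two split CVs (name suffixes ``c`` and ``o``).
    """
    charged = set(charged_residues)
    if site_charged_fraction <= fraction_threshold:
        return [crd_cv], (
            f"{crd_cv.name}: not split (charged fraction "
            f"{100 * site_charged_fraction:.1f}% <= "
            f"{100 * fraction_threshold:.0f}%)"
        )
    groups = {
        "A charged": [r for r in crd_cv.residues_a if r in charged],
        "A other": [r for r in crd_cv.residues_a if r not in charged],
        "B charged": [r for r in crd_cv.residues_b if r in charged],
        "B other": [r for r in crd_cv.residues_b if r not in charged],
    }
    for label, group in groups.items():
        if len(group) < 2 or not _has_nonadjacent_pair(group):
            return [crd_cv], (
                f"{crd_cv.name}: not split (group '{label}' lacks 2 "
                f"non-adjacent residues)"
            )
    out = []
    for suffix, key_a, key_b in (("c", "A charged", "B charged"),
                                 ("o", "A other", "B other")):
        res_a, res_b = groups[key_a], groups[key_b]
        out.append(
            CVDefinition(
                name=f"{crd_cv.name}{suffix}", kind="CRD",
                group_a=structure.heavy_indices(res_a),
                group_b=structure.heavy_indices(res_b),
                switching=crd_cv.switching,
                residues_a=tuple(res_a), residues_b=tuple(res_b),
            )
        )
    decision = (
        f"{crd_cv.name}: split into {out[0].name}/{out[1].name} (charged "
        f"fraction {100 * site_charged_fraction:.1f}% > "
        f"{100 * fraction_threshold:.0f}%, all groups have >= 2 "
        f"non-adjacent residues)"
    )
    return out, decision


# ------------------------------------------------------------- hill widths

def estimate_hill_widths(series: CVSeries, window_ps: float = 200.0,
                         scale: float = 1.0) -> dict[str, float]:
    """Hill widths = scaled sample std of each CV over a short unbiased run."""
    span = series.times[-1] - series.times[0]
    if span < window_ps:
        raise ValueError(
            f"series spans {span:.0f} ps < estimation window {window_ps:.0f} ps"
        )
    mask = series.times <= series.times[0] + window_ps
    widths = {}
    for k, name in enumerate(series.names):
        sd = float(np.std(series.values[mask, k], ddof=1))
        if sd <= 0:
            raise ValueError(f"CV {name!r} is constant over the window; "
                             "cannot derive a hill width")
        widths[name] = scale * sd
    return widths


# ----------------------------------------------------------------- bundle

@dataclass
class ProtocolBundle:
    """Complete, auditable metadynamics setup for one binding site."""

    cvs: list[CVDefinition]
    metad: MetaDParams
    schedule: RestraintSchedule
    audit: list[str] = field(default_factory=list)

    def cv(self, name: str) -> CVDefinition:
        for cv in self.cvs:
            if cv.name == name:
                return cv
        raise KeyError(name)


def build_protocol(structure: Structure, site: SiteDefinition,
                   domains: DomainMap | None = None, *,
                   core_label: str = "CORE",
                   switching: SwitchingParams | None = None,
                   interface_cutoff: float = 8.0,
                   charged_threshold: float = 0.25,
                   charged_set=DEFAULT_CHARGED_RESIDUES,
                   rog_mass_weighted: bool = True,
                   metad: MetaDParams | None = None,
                   widths_series: CVSeries | None = None,
                   unbiased_trajectory=None,
                   width_scale: float = 1.0,
                   durations_ns=(10.0, 40.0, 400.0, 150.0),
                   k_range=(10.0, 25.0),
                   target_fraction: float = 0.85) -> ProtocolBundle:
    """End-to-end protocol construction from structure + site (+ domains)."""
    rog_cv, cips, _frame, audit = build_binding_site_cvs(
        structure, site, switching=switching, rog_mass_weighted=rog_mass_weighted
    )
    cvs = [rog_cv, *cips]
    charged, _other = classify_residue_charge(structure, site, charged_set)
    fraction = len(charged) / len(site)
    audit.append(
        f"site charge: {len(charged)}/{len(site)} residues "
        f"({100 * fraction:.1f}%) in {sorted(charged_set)}"
    )
    if domains is not None:
        crds, crd_audit = build_crd_cvs(
            structure, site, domains, core_label=core_label,
            cutoff=interface_cutoff, switching=switching,
        )
        audit.extend(crd_audit)
        for crd in crds:
            split, decision = apply_charged_split(
                structure, crd, charged, fraction,
                fraction_threshold=charged_threshold,
            )
            audit.append(decision)
            cvs.extend(split)

    metad = metad or MetaDParams()
    if unbiased_trajectory is not None:
        # evaluate the final CV set on the short unbiased run, then take
        # per-CV fluctuations as hill widths
        from .cvs import evaluate_cv_series

        widths_series = evaluate_cv_series(
            unbiased_trajectory.coords, cvs, times=unbiased_trajectory.times
        )
    if widths_series is not None:
        widths = estimate_hill_widths(widths_series, scale=width_scale)
        missing = [cv.name for cv in cvs if cv.name not in widths]
        if missing:
            raise ValueError(f"width series lacks columns for CVs: {missing}")
        metad = replace(metad, widths={cv.name: widths[cv.name] for cv in cvs})

    rog_apo = radius_of_gyration(
        structure.coords[rog_cv.group_a], rog_cv.weights
    )
    audit.append(f"apo site gyration radius: {rog_apo:.4f} Å")
    schedule = build_restraint_schedule(
        rog_apo, durations_ns=durations_ns, k_range=k_range,
        target_fraction=target_fraction,
    )
    audit.append(
        f"restraint target: {target_fraction:.2f} x {rog_apo:.4f} = "
        f"{target_fraction * rog_apo:.4f} Å after "
        f"{sum(durations_ns[:3]):.0f} ns"
    )
    return ProtocolBundle(cvs=cvs, metad=metad, schedule=schedule, audit=audit)


# -------------------------------------------------------------- deck text

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _serials(indices: np.ndarray) -> str:
    return ",".join(str(int(i) + 1) for i in indices)  # 1-based atom serials


def _ps_to_steps(ps: float, timestep_fs: float, what: str) -> int:
    steps = ps * 1000.0 / timestep_fs
    if abs(steps - round(steps)) > 1e-6:
        raise ValueError(
            f"{what} of {ps} ps is not an integer number of {timestep_fs} fs "
            f"steps; choose a compatible timestep"
        )
    return int(round(steps))


def emit_metadynamics_input(bundle: ProtocolBundle, timestep_fs: float = 2.0) -> str:
    """Serialize a protocol bundle as a PLUMED-dialect input deck.

    The output is deterministic (same bundle -> byte-identical text) and
    survives :func:`parse_metadynamics_input` /
    :func:`render_deck` round trips unchanged.
    """
    missing = [cv.name for cv in bundle.cvs if cv.name not in bundle.metad.widths]
    if missing:
        raise ValueError(f"no hill width for CVs: {missing}")
    pace = _ps_to_steps(bundle.metad.deposition_ps, timestep_fs, "hill deposition period")
    exchange = _ps_to_steps(bundle.metad.exchange_ps, timestep_fs, "exchange period")
    lines = [
        "# pocket-shape metadynamics input deck",
        f"# timestep {_fmt(timestep_fs)} fs; bias-exchange period "
        f"{exchange} steps ({_fmt(bundle.metad.exchange_ps)} ps)",
        "UNITS LENGTH=A ENERGY=kcal/mol TIME=ps",
    ]
    for cv in bundle.cvs:
        if cv.kind == "ROG":
            lines.append(f"{cv.name}: GYRATION TYPE=RADIUS ATOMS={_serials(cv.group_a)}")
        else:
            sw = cv.switching
            lines.append(
                f"{cv.name}: COORDINATION GROUPA={_serials(cv.group_a)} "
                f"GROUPB={_serials(cv.group_b)} R_0={_fmt(sw.r0)} "
                f"D_0={_fmt(sw.d0)} NN={sw.n} MM={sw.m}"
            )
    names = ",".join(cv.name for cv in bundle.cvs)
    sigmas = ",".join(_fmt(bundle.metad.widths[cv.name]) for cv in bundle.cvs)
    lines.append(
        f"metad: METAD ARG={names} SIGMA={sigmas} "
        f"HEIGHT={_fmt(bundle.metad.hill_height)} PACE={pace} "
        f"BIASFACTOR={_fmt(bundle.metad.bias_factor)}"
    )
    # moving upper wall on the site gyration radius
    sched = bundle.schedule
    t = 0.0
    knots: list[tuple[int, float, float]] = []
    for phase in sched.phases:
        t += phase.duration_ns
        if phase.wall == "none":
            continue
        if not knots:
            start_steps = _ps_to_steps((t - phase.duration_ns) * 1000.0,
                                       timestep_fs, "restraint phase start")
            knots.append((start_steps, phase.center_start, phase.k_start))
        knots.append((_ps_to_steps(t * 1000.0, timestep_fs, "restraint phase end"),
                      phase.center_end, phase.k_end))
    parts = [f"restraint: MOVINGRESTRAINT ARG={bundle.cvs[0].name} VERSE=U"]
    for i, (step, at, kappa) in enumerate(knots):
        parts.append(f"STEP{i}={step} AT{i}={_fmt(at)} KAPPA{i}={_fmt(kappa)}")
    lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


@dataclass
class ParsedDeck:
    """Token-preserving parse of an emitted input deck."""

    lines: list[tuple[str, ...] | str]  # token tuples, or raw comment strings

    def directive(self, action: str) -> dict[str, str]:
        """Key/value map of the first directive with the given action."""
        for entry in self.lines:
            if isinstance(entry, str):
                continue
            tokens = list(entry)
            if tokens and tokens[0].endswith(":"):
                tokens = tokens[1:]
            if tokens and tokens[0] == action:
                out = {}
                for tok in tokens[1:]:
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        out[key] = val
                return out
        raise KeyError(f"no {action} directive in deck")


def parse_metadynamics_input(text: str) -> ParsedDeck:
    lines: list[tuple[str, ...] | str] = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        if raw.lstrip().startswith("#"):
            lines.append(raw)
        else:
            lines.append(tuple(raw.split()))
    return ParsedDeck(lines)


def render_deck(deck: ParsedDeck) -> str:
    out = []
    for entry in deck.lines:
        out.append(entry if isinstance(entry, str) else " ".join(entry))
    return "\n".join(out) + "\n"


# ------------------------------------------------------------- YAML config

def protocol_config_to_yaml(site: SiteDefinition, domains: DomainMap | None,
                            path, **settings) -> None:
    """Persist site, domain map and thresholds as a YAML config file."""
    doc = {
        "site": {"residues": list(site.residues), "provenance": site.provenance},
        "domains": dict(domains.mapping) if domains else None,
        "settings": settings,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def protocol_config_from_yaml(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    site = SiteDefinition(tuple(doc["site"]["residues"]),
                          provenance=doc["site"].get("provenance", "user"))
    domains = DomainMap(doc["domains"]) if doc.get("domains") else None
    return site, domains, doc.get("settings", {})
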