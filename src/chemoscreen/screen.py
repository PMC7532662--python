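"""Scoring of siRNA pool x drug sensitization screens.

A drug-modifier RNAi screen asks which gene knockdowns make cells more
sensitive to a drug than expected from the knockdown and drug effects
alone.  Each well reports a viability absorbance (CCK-8 OD).  With

    Rc  knockdown siRNA, vehicle
    Cc  nontargeting siRNA, vehicle
    Cd  nontargeting siRNA, drug
    Rd  knockdown siRNA, drug

the sensitization index is

    SI = (Rc/Cc) * (Cd/Cc) - Rd/Cc

i.e. the Bliss-style multiplicative expectation for the combined
condition minus the observed combined viability, both normalized to the
untreated control.  SI > 0 means the combination kills more than
expected (sensitization); SI < 0 means protection.  A nontargeting well
scores exactly 0.

``score_screen`` applies this per target per replicate, averages over
replicates, averages target scores into gene scores, and calls hits at a
strict ``SI > threshold`` (default 0.1).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "sensitization_index",
    "score_screen",
    "pool_design",
    "overlap_candidates",
    "validate_plate",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ["target_id", "gene", "is_control", "condition", "replicate", "od"]

CONDITIONS = ("vehicle", "drug")


def sensitization_index(rc, cc, cd, rd):
    """Sensitization index for one target.

    Parameters are the four absorbances (scalars or arrays): ``rc``
    knockdown/vehicle, ``cc`` control/vehicle, ``cd`` control/drug,
    ``rd`` knockdown/drug.  All must be strictly positive.

    Returns ``(rc/cc)*(cd/cc) - rd/cc`` (dimensionless).
    """
    rc, cc, cd, rd = (np.asarray(v, dtype=float) for v in (rc, cc, cd, rd))
    for name, v in zip(("rc", "cc", "cd", "rd"), (rc, cc, cd, rd)):
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError(f"absorbance {name!r} must be finite and > 0")
    out = (rc / cc) * (cd / cc) - rd / cc
    return out.item() if out.ndim == 0 else out


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format screen plate table and return it normalized.

    Required columns: target_id, gene, is_control, condition
    ('vehicle'|'drug'), replicate (int >= 1), od (> 0).  The
    (target_id, condition, replicate) key must be unique and each
    condition needs at least one nontargeting control well.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    plate = plate.copy()
    plate["is_control"] = plate["is_control"].astype(bool)
    plate["condition"] = plate["condition"].astype(str).str.lower()
    bad_cond = set(plate["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
    plate["replicate"] = plate["replicate"].astype(int)
    if (plate["replicate"] < 1).any():
        raise ValueError("replicate indices must be >= 1")
    od = plate["od"].astype(float)
    if not np.all(np.isfinite(od)) or (od <= 0).any():
        raise ValueError("all od values must be finite and > 0")
    plate["od"] = od
    dup = plate.duplicated(subset=["target_id", "condition", "replicate"])
    if dup.any():
        keys = plate.loc[dup, ["target_id", "condition", "replicate"]].iloc[0].tolist()
        raise ValueError(f"duplicate well key (target, condition, replicate), e.g. {keys}")
    controls = plate[plate["is_control"]]
    for cond in CONDITIONS:
        if (controls["condition"] == cond).sum() == 0:
            raise ValueError(f"no nontargeting control wells in condition {cond!r}")
    return plate


def _control_summary(values: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return float(np.median(values))
    raise ValueError(f"control_stat must be 'mean' or 'median', got {stat!r}")


def score_screen(
    plate: pd.DataFrame,
    threshold: float = 0.1,
    control_stat: str = "mean",
) -> pd.DataFrame:
    """Score every targeting siRNA on a plate and call hits.

    Per replicate, the control levels Cc (vehicle) and Cd (drug) are the
    mean (or median, ``control_stat``) OD of the nontargeting wells of
    that replicate; targets then get one SI per replicate from their own
    Rc/Rd wells, averaged into ``si_mean``.  Gene score = mean of the
    gene's target ``si_mean`` values.  ``hit`` is strict
    ``si_mean > threshold``; a target missing a well in either condition
    is kept with ``status='unevaluable'`` (SI NaN, not a hit) so plate
    QC stays visible.

    Returns a per-target DataFrame with columns target_id, gene,
    si_rep<k>, n_replicates, si_mean, gene_si_mean, hit, status.
    """
    plate = validate_plate(plate)
    controls = plate[plate["is_control"]]
    targets = plate[~plate["is_control"]]
    if targets.empty:
        raise ValueError("plate contains no targeting wells")

    # per-replicate control levels; a replicate missing control wells is unusable
    ctrl = {}
    for (cond, rep), grp in controls.groupby(["condition", "replicate"]):
        ctrl[(cond, rep)] = _control_summary(grp["od"].to_numpy(), control_stat)

    replicates = sorted(targets["replicate"].unique())
    rows = []
    for (tid, gene), grp in targets.groupby(["target_id", "gene"], sort=True):
        by_key = {(c, r): o for c, r, o in zip(grp["condition"], grp["replicate"], grp["od"])}
        si_reps: dict[int, float] = {}
        for rep in sorted({r for (_, r) in by_key}):
            key_ok = (
                ("vehicle", rep) in by_key
                and ("drug", rep) in by_key
                and ("vehicle", rep) in ctrl
                and ("drug", rep) in ctrl
            )
            if key_ok:
                si_reps[rep] = sensitization_index(
                    rc=by_key[("vehicle", rep)],
                    cc=ctrl[("vehicle", rep)],
                    cd=ctrl[("drug", rep)],
                    rd=by_key[("drug", rep)],
                )
        row = {"target_id": tid, "gene": gene}
        for rep in replicates:
            row[f"si_rep{rep}"] = si_reps.get(rep, np.nan)
        row["n_replicates"] = len(si_reps)
        if si_reps:
            row["si_mean"] = float(np.mean(list(si_reps.values())))
            row["status"] = "ok"
        else:
            row["si_mean"] = np.nan
            row["status"] = "unevaluable"
        rows.append(row)
    res = pd.DataFrame(rows)
    res["hit"] = (res["si_mean"] > threshold) & res["status"].eq("ok")
    gene_mean = res.groupby("gene")["si_mean"].mean()
    res["gene_si_mean"] = res["gene"].map(gene_mean)
    return res


def pool_design(genes: Sequence[str], duplexes_per_gene: int = 3) -> pd.DataFrame:
    """Design an siRNA pool manifest: genes x duplexes plus one nontargeting control.

    Returns a DataFrame with columns target_id, gene, duplex, is_control.
    The targeting-record count is ``len(genes) * duplexes_per_gene``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene names: {dups}")
    if duplexes_per_gene < 1:
        raise ValueError("duplexes_per_gene must be >= 1")
    rows = [
        {"target_id": f"{g}_si{d}", "gene": g, "duplex": d, "is_control": False}
        for g in genes
        for d in range(1, duplexes_per_gene + 1)
    ]
    rows.append({"target_id": "NT_control", "gene": "nontargeting", "duplex": 0, "is_control": True})
    manifest = pd.DataFrame(rows)
    manifest.attrs["n_targeting"] = len(genes) * duplexes_per_gene
    return manifest


def overlap_candidates(
    per_patient_up: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    resistant_up: Iterable[str],
    mode: str = "both",
) -> set[str]:
    """Candidate-gene set logic for post-treatment vs pre-treatment up-lists.

    ``per_patient_up`` holds the genes upregulated in each patient's
    post-treatment residual; ``resistant_up`` the genes upregulated in
    resistant vs sensitive baselines.  ``mode='both'`` intersects across
    patients before the final intersection with ``resistant_up``;
    ``mode='at_least_one'`` takes the union across patients instead.
    """
    if isinstance(per_patient_up, Mapping):
        sets = [set(v) for v in per_patient_up.values()]
    else:
        sets = [set(v) for v in per_patient_up]
    if not sets:
        raise ValueError("need at least one per-patient gene list")
    if mode == "both":
        pooled = set.intersection(*sets)
    elif mode == "at_least_one":
        pooled = set.union(*sets)
    else:
        raise ValueError(f"mode must be 'both' or 'at_least_one', got {mode!r}")
    return pooled & set(resistant_up)
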