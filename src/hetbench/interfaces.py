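"""File dialects, validators and the directory-level scoring routine.

Prediction dialects (all plain text, tab separated, no headers):

* 1A — a single purity in [0, 1];
* 1B — a single non-negative integer subclone count;
* 1C — rows of ``cluster_id  n_ssms  cp``;
* 2A — one 1-based cluster label per line, in truth SNV order;
* 2B — a dense N x N symmetric cocluster probability matrix, unit diagonal;
* 3A — rows of ``cluster_id  parent_id`` with 0 denoting the germline root;
* 3B — a dense N x N ancestor-descendant probability matrix.

A truth bundle is a directory holding ``purity.txt``, ``clusters.tsv``
(``cluster_id  parent_id  n_ssms  cp``) and ``assignments.tsv``
(``snv_id  cluster_id``); SNV order in the assignment file is the binding
index for the 2A/2B/3B matrix formats.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hetbench.core import (
    GERMLINE,
    HardAssignment,
    HetbenchError,
    PhylogenyTruth,
    RelationshipMatrices,
    Subclone,
)
from hetbench.cohort import Cohort
from hetbench.predictions import SUBCHALLENGES, PredictionSet, score_prediction_set
from hetbench.scoring import ClusterProfile

logger = logging.getLogger("hetbench")

#: Dense pairwise matrices beyond this many SNVs are refused (O(N^2) memory).
MAX_MATRIX_SNVS = 20_000

DIALECT_VERSION = "1"


class ValidationError(HetbenchError):
    """A file failed dialect validation; the message names the line."""


def _fail(path, line, msg) -> None:
    raise ValidationError(f"{path}:{line}: {msg}")


def _read_lines(path) -> list[str]:
    text = Path(path).read_text()
    return [ln for ln in text.splitlines() if ln.strip() != ""]


def _parse_float(tok: str, path, line) -> float:
    try:
        v = float(tok)
    except ValueError:
        _fail(path, line, f"not a number: {tok!r}")
    if not np.isfinite(v):
        _fail(path, line, f"non-finite value: {tok!r}")
    return v


# ---------------------------------------------------------------------------
# prediction dialects
# ---------------------------------------------------------------------------

def read_prediction(path, subchallenge: str):
    """Parse and validate one prediction file; returns the typed object."""
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        _fail(path, 1, "empty file")
    sub = subchallenge.upper()
    if sub == "1A":
        v = _parse_float(lines[0].strip(), path, 1)
        if not (0.0 <= v <= 1.0):
            _fail(path, 1, f"purity {v} outside [0, 1]")
        return v
    if sub == "1B":
        tok = lines[0].strip()
        try:
            v = int(tok)
        except ValueError:
            _fail(path, 1, f"not an integer: {tok!r}")
        if v < 0:
            _fail(path, 1, f"negative subclone count {v}")
        return v
    if sub == "1C":
        clusters = []
        for i, ln in enumerate(lines, 1):
            parts = ln.split("\t")
            if len(parts) != 3:
                _fail(path, i, f"expected 3 columns, got {len(parts)}")
            cid = int(_parse_float(parts[0], path, i))
            n = int(_parse_float(parts[1], path, i))
            cp = _parse_float(parts[2], path, i)
            if not (0.0 <= cp <= 1.0):
                _fail(path, i, f"cp {cp} outside [0, 1]")
            if n < 1:
                _fail(path, i, f"cluster {cid} has no SNVs")
            clusters.append((cid, n, cp))
        return ClusterProfile(clusters)
    if sub == "2A":
        labels = []
        for i, ln in enumerate(lines, 1):
            v = int(_parse_float(ln.strip(), path, i))
            if v < 1:
                _fail(path, i, f"cluster labels are 1-based, got {v}")
            labels.append(v)
        return HardAssignment(np.asarray(labels))
    if sub in ("2B", "3B"):
        rows = [ln.split("\t") for ln in lines]
        n = len(rows)
        if n > MAX_MATRIX_SNVS:
            _fail(path, 1, f"matrix of {n} SNVs exceeds the {MAX_MATRIX_SNVS} cap")
        mat = np.empty((n, n))
        for i, parts in enumerate(rows, 1):
            if len(parts) != n:
                _fail(path, i, f"expected {n} columns, got {len(parts)}")
            mat[i - 1] = [_parse_float(t, path, i) for t in parts]
        if mat.min() < -1e-9 or mat.max() > 1 + 1e-9:
            _fail(path, 1, "matrix entries must lie in [0, 1]")
        if sub == "2B":
            asym = np.argwhere(np.abs(mat - mat.T) > 1e-6)
            if asym.size:
                _fail(path, int(asym[0, 0]) + 1, "matrix is not symmetric")
            bad = np.argwhere(np.abs(np.diag(mat) - 1.0) > 1e-6)
            if bad.size:
                _fail(path, int(bad[0, 0]) + 1, "diagonal entries must be 1")
        return mat
    if sub == "3A":
        tree: dict[int, int] = {}
        for i, ln in enumerate(lines, 1):
            parts = ln.split("\t")
            if len(parts) != 2:
                _fail(path, i, f"expected 2 columns, got {len(parts)}")
            cid = int(_parse_float(parts[0], path, i))
            pid = int(_parse_float(parts[1], path, i))
            if cid in tree:
                _fail(path, i, f"duplicate cluster {cid}")
            tree[cid] = pid
        for cid, pid in tree.items():
            if pid != GERMLINE and pid not in tree:
                _fail(path, 1, f"cluster {cid} has unknown parent {pid}")
        return tree
    raise ValidationError(f"unknown subchallenge {subchallenge!r}")


def write_prediction(obj, path, subchallenge: str) -> None:
    """Serialize one prediction in its subchallenge dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sub = subchallenge.upper()
    if sub == "1A":
        path.write_text(f"{float(obj):.10g}\n")
    elif sub == "1B":
        path.write_text(f"{int(obj)}\n")
    elif sub == "1C":
        rows = [f"{cid}\t{n}\t{cp:.10g}" for cid, n, cp in obj.clusters]
        path.write_text("\n".join(rows) + "\n")
    elif sub == "2A":
        labels = obj.labels if isinstance(obj, HardAssignment) else np.asarray(obj)
        path.write_text("\n".join(str(int(v)) for v in labels) + "\n")
    elif sub in ("2B", "3B"):
        mat = np.asarray(obj, dtype=float)
        with path.open("w") as fh:
            for row in mat:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
    elif sub == "3A":
        rows = [f"{cid}\t{pid}" for cid, pid in sorted(obj.items())]
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ValidationError(f"unknown subchallenge {subchallenge!r}")


# ---------------------------------------------------------------------------
# truth bundles
# ---------------------------------------------------------------------------

def write_truth(truth: PhylogenyTruth, bundle_dir) -> None:
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    (d / "purity.txt").write_text(f"{truth.purity:.10g}\n")
    rows = [f"{s.id}\t{s.parent_id}\t{s.n_ssms}\t{s.cp:.10g}" for s in truth.subclones]
    (d / "clusters.tsv").write_text("\n".join(rows) + "\n")
    arows = [f"{snv}\t{cl}" for snv, cl in truth.assignment.items()]
    (d / "assignments.tsv").write_text("\n".join(arows) + "\n")


def read_truth(bundle_dir) -> PhylogenyTruth:
    """Load a truth bundle, enforcing all tree invariants at load time."""
    d = Path(bundle_dir)
    purity = _parse_float((d / "purity.txt").read_text().strip(), d / "purity.txt", 1)
    subclones = []
    cpath = d / "clusters.tsv"
    for i, ln in enumerate(_read_lines(cpath), 1):
        parts = ln.split("\t")
        if len(parts) != 4:
            _fail(cpath, i, f"expected 4 columns, got {len(parts)}")
        subclones.append(
            Subclone(
                int(parts[0]), int(parts[1]), _parse_float(parts[3], cpath, i), int(parts[2])
            )
        )
    apath = d / "assignments.tsv"
    assignment: dict = {}
    for i, ln in enumerate(_read_lines(apath), 1):
        parts = ln.split("\t")
        if len(parts) != 2:
            _fail(apath, i, f"expected 2 columns, got {len(parts)}")
        snv = parts[0]
        try:
            snv = int(snv)
        except ValueError:
            pass
        if snv in assignment:
            _fail(apath, i, f"duplicate assignment for SNV {snv!r}")
        assignment[snv] = int(parts[1])
    try:
        return PhylogenyTruth(purity=purity, subclones=subclones, assignment=assignment)
    except HetbenchError as exc:
        raise ValidationError(f"{bundle_dir}: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort I/O and directory scoring
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir, matrix_limit: int = 2000) -> pd.DataFrame:
    """Write a cohort to disk (truth bundles + prediction files + manifest);
    returns the manifest.

    Dense 2B/3B matrices are skipped (with a log message) for tumors above
    ``matrix_limit`` SNVs to keep the on-disk cohort at a sane size.  A
    prediction whose SNV universe differs from the truth's (false negatives
    dropped, false positives invented) carries its universe in ``snvs.txt``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tid, truth in cohort.truths.items():
        write_truth(truth, out / "truth" / tid)
    rows = []
    for (tid, alg), pred in cohort.predictions.items():
        pdir = out / "predictions" / alg / tid
        n = len(pred.snv_ids)
        write_matrices = n <= matrix_limit
        if not write_matrices:
            logger.info("%s/%s: %d SNVs, skipping dense 2B/3B files", alg, tid, n)
        mats = pred.get_matrices() if write_matrices else None
        payload = {
            "1A": pred.purity,
            "1B": pred.n_clusters,
            "1C": pred.profile,
            "2A": pred.assignment,
            "2B": pred.get_cocluster() if write_matrices else None,
            "3A": pred.tree,
            "3B": mats.ancestor_descendant if mats is not None else None,
        }
        wrote_any = False
        for sub, obj in payload.items():
            if obj is None:
                continue
            fpath = pdir / f"sc{sub}.txt"
            write_prediction(obj, fpath, sub)
            wrote_any = True
            rows.append((tid, alg, sub, str(fpath.relative_to(out))))
        if wrote_any and list(pred.snv_ids) != list(cohort.truths[tid].snv_ids):
            (pdir / "snvs.txt").write_text(
                "\n".join(str(s) for s in pred.snv_ids) + "\n"
            )
    manifest = pd.DataFrame(rows, columns=["tumor", "algorithm", "subchallenge", "path"])
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.meta.to_csv(out / "tumors.csv", index=False)
    return manifest


def load_prediction_set(pred_dir, snv_ids) -> PredictionSet:
    """Assemble a PredictionSet from a per-tumor prediction directory.

    sc3B scoring needs a cocluster matrix alongside the ancestor-descendant
    matrix; the 2B file provides it when present.
    """
    d = Path(pred_dir)
    snv_file = d / "snvs.txt"
    if snv_file.exists():
        ids = []
        for ln in _read_lines(snv_file):
            tok = ln.strip()
            try:
                ids.append(int(tok))
            except ValueError:
                ids.append(tok)
        snv_ids = ids
    kw: dict = {"snv_ids": list(snv_ids)}
    mapping = {
        "1A": "purity",
        "1B": "n_clusters",
        "1C": "profile",
        "2A": "assignment",
        "2B": "cocluster",
        "3A": "tree",
    }
    for sub, attr in mapping.items():
        f = d / f"sc{sub}.txt"
        if f.exists():
            kw[attr] = read_prediction(f, sub)
    f3b = d / "sc3B.txt"
    if f3b.exists():
        ad = read_prediction(f3b, "3B")
        cc = kw.get("cocluster")
        if cc is None and "assignment" in kw:
            lab = kw["assignment"].labels
            cc = (lab[:, None] == lab[None, :]).astype(float)
        if cc is not None:
            kw["matrices"] = RelationshipMatrices.from_soft(cc, ad)
    return PredictionSet(**kw)


def score_command(truth_dir, pred_dir, out_csv=None) -> pd.DataFrame:
    """Score every {tumor, algorithm, subchallenge} found on disk.

    ``truth_dir`` holds one truth bundle per tumor; ``pred_dir`` holds
    ``<algorithm>/<tumor>/sc<sub>.txt`` files.  Unparseable or failing
    predictions are recorded as missing with a reason — they are not scored
    zero — and the run continues.
    """
    truth_dir, pred_dir = Path(truth_dir), Path(pred_dir)
    truths = {p.name: read_truth(p) for p in sorted(truth_dir.iterdir()) if p.is_dir()}
    if not truths:
        raise ValidationError(f"no truth bundles under {truth_dir}")
    rows = []
    for alg_dir in sorted(p for p in pred_dir.iterdir() if p.is_dir()):
        for tid, truth in truths.items():
            tdir = alg_dir / tid
            if not tdir.is_dir():
                continue
            try:
                pred = load_prediction_set(tdir, truth.snv_ids)
                scores = score_prediction_set(truth, pred)
            except HetbenchError as exc:
                logger.warning("skipping %s/%s: %s", alg_dir.name, tid, exc)
                rows.append((tid, alg_dir.name, None, np.nan, f"error: {exc}"))
                continue
            for sub in SUBCHALLENGES:
                if sub in scores:
                    rows.append((tid, alg_dir.name, sub, scores[sub], ""))
    df = pd.DataFrame(
        rows, columns=["tumor", "algorithm", "subchallenge", "s_raw", "note"]
    )
    if df["s_raw"].notna().sum() == 0:
        raise ValidationError("no parseable predictions found")
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def read_config(path) -> dict[str, str]:
    """Flat key=value config; '#' starts a comment."""
    out: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), 1):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            _fail(path, i, "expected key=value")
        k, v = ln.split("=", 1)
        out[k.strip()] = v.strip()
    return out
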