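"""End-to-end orchestration: images + masks + ratings -> reports.

Two tracks mirror the analysis workflow:

* the contrast track turns a bundle of scenes (equirectangular renders
  plus block masks and per-setting preference ratings) into region
  correlates, external/internal contrast triples in IPT and CAM16,
  per-scene working areas, bright-to-dark trend fits, and the
  dimension-by-dimension IPT/CAM16 correlation;
* the similarity track turns a subjects x pairs rating matrix into a
  Wilcoxon table, a dissimilarity matrix, non-metric MDS embeddings for
  k = 1..k_max, and PCoA scree fractions.

Every run writes a metadata record carrying the full configuration and
its hash; identical configuration and seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cam16 import cam16_viewing_conditions
from .contrast import (
    correlate_spaces,
    fit_contrast_trend,
    region_correlates,
    scene_contrast,
    working_area,
)
from .ordinal import (
    bray_curtis,
    mean_difference_matrix,
    nmds,
    pcoa_scree,
    rating_profiles,
    wilcoxon_signed_rank,
)
from .scene import (
    EquirectImage,
    SceneMask,
    apply_scene_mask,
    decompose_blocks,
    extract_perspective_view,
    load_image,
    save_image,
)
from .synth import LIGHT_SETTINGS, SyntheticSceneSpec, gen_scene

logger = logging.getLogger("cabinlight")

#: Scene archetypes ordered from externally bright to dark (a-d).
SCENE_ORDER = ("sun_city", "countryside", "forest", "night")

#: Default luminaire settings of the immersive part (L2 skipped; L8 = no
#: light, rendered at a single level), yielding 31 images per scene.
DEFAULT_SETTINGS = ("L1", "L3", "L4", "L5", "L6", "L7")
DEFAULT_LEVELS = (1, 2, 3, 4, 5)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; all stochastic steps are seeded."""

    out_dir: str = "run"
    block: int = 32
    fov: float = 86.0
    yaw: float = 0.0
    pitch: float = 0.0
    use_view: bool = True
    view_size: tuple[int, int] = (1024, 512)
    spaces: tuple[str, ...] = ("IPT", "CAM16")
    L_A: float = 20.0
    Y_b: float = 20.0
    surround: str = "average"
    threshold: float = 5.0
    alpha: float = 0.05
    restarts: int = 20
    k_max: int = 4
    dissimilarity: str = "bray_curtis"  # or "mean_difference"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("significance level alpha must lie in (0, 1)")
        if self.dissimilarity not in ("bray_curtis", "mean_difference"):
            raise ValueError(f"unknown dissimilarity method {self.dissimilarity!r}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spaces"] = list(self.spaces)
        d["view_size"] = list(self.view_size)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("spaces",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "view_size" in raw:
            raw["view_size"] = tuple(raw["view_size"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc


def _write_metadata(cfg: RunConfig, out: Path, extra: dict | None = None) -> None:
    meta = {
        "package": "cabinlight",
        "version": __version__,
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash(),
    }
    if extra:
        meta.update(extra)
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def project_mask(
    mask: SceneMask,
    equirect_height: int,
    block: int,
    yaw: float = 0.0,
    pitch: float = 0.0,
    fov: float = 86.0,
    view_size: tuple[int, int] = (1024, 512),
) -> SceneMask:
    """Project an equirect block mask into the block grid of a view.

    Pushes the per-pixel external indicator through the same gnomonic
    projection used for the image and marks a view block external when
    the external indicator covers more than half of it.
    """
    ext_pix = np.kron(
        mask.external, np.ones((block, block), dtype=bool)
    )
    indicator = EquirectImage(
        np.repeat((ext_pix * 255).astype(np.uint8)[..., None], 3, axis=2)
    )
    view = extract_perspective_view(
        indicator, yaw=yaw, pitch=pitch, fov=fov, out_size=view_size
    )
    h, w = view.pixels.shape[:2]
    grid = view.pixels[..., 0].reshape(h // block, block, w // block, block)
    return SceneMask(grid.mean(axis=(1, 3)) > 127.0)


def simulate_bundle(
    out_dir,
    seed: int = 0,
    scenes=SCENE_ORDER,
    settings=DEFAULT_SETTINGS,
    levels=DEFAULT_LEVELS,
    height: int = 512,
    block: int = 32,
    include_baseline: bool = True,
    view: bool = True,
    fov: float = 86.0,
    yaw: float = 0.0,
    pitch: float = 0.0,
    view_size: tuple[int, int] = (1024, 512),
) -> pd.DataFrame:
    """Render a synthetic study bundle to disk and return its index.

    Writes one PNG and mask JSON per (scene, setting, level), the
    no-light baseline L8 once per scene, plus ``ratings.csv`` with a
    synthetic mean preference rating per image (7-point scale, highest
    where internal and external lightness are balanced, with seeded
    ordinal jitter).  The default grid (4 scenes x 6 settings x 5
    levels + 4 baselines) matches the 124-image study layout.  With
    ``view=True`` (the default, matching the pipeline's default of
    analyzing the extracted rating view) masks are written in the view's
    block geometry via :func:`project_mask`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 924]))
    rows = []
    combos = [(s, st, lv) for s in scenes for st in settings for lv in levels]
    if include_baseline:
        combos += [(s, "L8", 1) for s in scenes]
    for scene, setting, level in combos:
        spec = SyntheticSceneSpec(
            archetype=scene,
            setting=setting,
            level=level,
            seed=int(
                np.random.SeedSequence(
                    [seed, SCENE_ORDER.index(scene) if scene in SCENE_ORDER else 99]
                ).generate_state(1)[0]
                % 2**31
            ),
            height=height,
            block=block,
        )
        img, mask = gen_scene(spec)
        stem = f"{scene}_{setting}_lv{level}"
        save_image(img, out / f"{stem}.png")
        if view:
            mask = project_mask(
                mask, height, block, yaw=yaw, pitch=pitch, fov=fov, view_size=view_size
            )
        mask.to_json(out / f"{stem}.mask.json")
        # Latent preference rule: best where interior matches exterior.
        if view:
            analyzed = extract_perspective_view(
                img, yaw=yaw, pitch=pitch, fov=fov, out_size=view_size
            )
        else:
            analyzed = img
        grid = decompose_blocks(analyzed, block)
        ext, intr, _ = apply_scene_mask(grid, mask)
        dj = scene_contrast(
            region_correlates(ext, "IPT"), region_correlates(intr, "IPT")
        ).dJ
        rating = float(np.clip(np.round(7.0 - abs(dj) / 22.0 + rng.normal(0, 0.25)), 1, 7))
        rows.append(
            {"scene": scene, "setting": setting, "level": level, "image": f"{stem}.png",
             "mask": f"{stem}.mask.json", "rating": rating}
        )
    index = pd.DataFrame(rows)
    index.to_csv(out / "ratings.csv", index=False)
    return index


def run_contrast_pipeline(cfg: RunConfig, bundle_dir) -> dict:
    """Run the contrast track on a simulated or user-provided bundle.

    ``bundle_dir`` must contain ``ratings.csv`` (columns scene, setting,
    level, image, mask, rating) with images and masks alongside.  A
    record whose mask file is missing is skipped with a logged warning.
    Writes contrasts.csv, working_areas.json, trend_fits.json,
    space_correlation.json and run_metadata.json to ``cfg.out_dir``.
    """
    bundle = Path(bundle_dir)
    ratings_path = bundle / "ratings.csv"
    if not ratings_path.exists():
        raise FileNotFoundError(f"no ratings.csv in {bundle}")
    index = pd.read_csv(ratings_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vc = cam16_viewing_conditions(L_A=cfg.L_A, Y_b=cfg.Y_b, surround=cfg.surround)

    records = []
    skipped = 0
    for _, row in index.iterrows():
        mask_path = bundle / row["mask"]
        if not mask_path.exists():
            logger.warning("skipping %s: mask %s missing", row["image"], row["mask"])
            skipped += 1
            continue
        img = load_image(bundle / row["image"])
        mask = SceneMask.from_json(mask_path)
        if cfg.use_view and isinstance(img, EquirectImage):
            img = extract_perspective_view(
                img, yaw=cfg.yaw, pitch=cfg.pitch, fov=cfg.fov, out_size=cfg.view_size
            )
            # The mask is defined on the source block grid; views extracted
            # at the source resolution keep the grid geometry.
        grid = decompose_blocks(img, cfg.block)
        if mask.shape != (grid.n_rows, grid.n_cols):
            logger.warning(
                "skipping %s: mask shape %s does not match grid", row["image"], mask.shape
            )
            skipped += 1
            continue
        ext, intr, frac = apply_scene_mask(grid, mask)
        rec = dict(row)
        for space in cfg.spaces:
            sc = region_correlates(ext, space, vc)
            il = region_correlates(intr, space, vc)
            tri = scene_contrast(
                sc, il, scene=row["scene"], setting=row["setting"],
                level=int(row["level"]),
            )
            rec[f"dJ_{space}"] = tri.dJ
            rec[f"dc_{space}"] = tri.dc
            rec[f"dh_{space}"] = tri.dh
            rec[f"J_sc_{space}"], rec[f"J_il_{space}"] = float(sc.J), float(il.J)
            rec[f"c_sc_{space}"], rec[f"c_il_{space}"] = float(sc.c), float(il.c)
            rec[f"h_sc_{space}"], rec[f"h_il_{space}"] = float(sc.h), float(il.h)
        rec["external_fraction"] = frac
        records.append(rec)
    if not records:
        raise ValueError("no usable records in the bundle")
    table = pd.DataFrame(records)
    table.to_csv(out / "contrasts.csv", index=False, float_format="%.10g")

    # Working areas per scene and space.
    from .contrast import ContrastTriple

    areas = []
    for space in cfg.spaces:
        for scene, sub in table.groupby("scene", sort=True):
            contrasts = [
                ContrastTriple(
                    dJ=r[f"dJ_{space}"], dc=r[f"dc_{space}"], dh=r[f"dh_{space}"],
                    space=space, scene=scene,
                    setting=f"{r['setting']}_lv{int(r['level'])}",
                    level=int(r["level"]),
                )
                for _, r in sub.iterrows()
            ]
            setting_ratings = {
                f"{r['setting']}_lv{int(r['level'])}": float(r["rating"])
                for _, r in sub.iterrows()
            }
            wa = working_area(contrasts, setting_ratings, cfg.threshold, scene=scene)
            entry = wa.as_dict()
            entry["space"] = space
            areas.append(entry)
    (out / "working_areas.json").write_text(json.dumps(areas, indent=2, sort_keys=True))

    # Bright-to-dark trend fits over the scene order, preferred points only
    # (falling back to all points when too few are preferred).
    order = {s: i for i, s in enumerate(SCENE_ORDER)}
    table["scene_order"] = table["scene"].map(order)
    fits = []
    for space in cfg.spaces:
        pref = table[table["rating"] >= cfg.threshold]
        pool = pref if pref["scene"].nunique() >= 3 else table
        for dim in ("dJ", "dc", "dh"):
            y = pool[f"{dim}_{space}"]
            ok = y.notna() & pool["scene_order"].notna()
            if ok.sum() < 3 or pool.loc[ok, "scene_order"].nunique() < 2:
                continue
            fit = fit_contrast_trend(
                pool.loc[ok, "scene_order"], y[ok], degree=1,
                predictor="scene_order", response=f"{dim}_{space}",
            )
            entry = fit.as_dict()
            entry["space"] = space
            entry["significant"] = fit.p_value < cfg.alpha
            fits.append(entry)
    (out / "trend_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))

    # IPT vs CAM16 correlation, dimension by dimension.
    correlation = {}
    if {"IPT", "CAM16"} <= set(cfg.spaces):
        for dim, circ in (("dJ", False), ("dc", False), ("dh", True)):
            a = table[f"{dim}_IPT"].to_numpy()
            b = table[f"{dim}_CAM16"].to_numpy()
            try:
                correlation[dim] = correlate_spaces(a, b, circular=circ)
            except ValueError as exc:
                correlation[dim] = {"error": str(exc)}
    (out / "space_correlation.json").write_text(
        json.dumps(correlation, indent=2, sort_keys=True)
    )

    _write_metadata(cfg, out, {"n_records": len(records), "n_skipped": skipped})
    return {
        "contrasts": table,
        "working_areas": areas,
        "trend_fits": fits,
        "space_correlation": correlation,
        "n_skipped": skipped,
    }


def run_similarity_pipeline(cfg: RunConfig, ratings: pd.DataFrame) -> dict:
    """Run the ordinal similarity track on a subjects x pairs rating matrix.

    Columns label paired comparisons (tuples or "A|B" strings).  Writes
    wilcoxon.csv, dissimilarity.csv, nmds.json, scree.json and
    run_metadata.json to ``cfg.out_dir``.  The Wilcoxon table tests
    every pair column against the reference column with the highest
    mean difference rating.
    """
    if ratings.empty:
        raise ValueError("rating table is empty")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cols = list(ratings.columns)
    parsed = [c if isinstance(c, tuple) else tuple(str(c).split("|")) for c in cols]
    if any(len(p) != 2 for p in parsed):
        raise ValueError("rating columns must label item pairs as (a, b) or 'a|b'")

    ref_idx = int(np.argmax([ratings[c].mean() for c in cols]))
    ref = cols[ref_idx]
    wilcox_rows = []
    for c, pair in zip(cols, parsed):
        base = {"pair": "|".join(pair), "reference": "|".join(parsed[ref_idx]),
                "mean": float(ratings[c].mean())}
        if c == ref:
            wilcox_rows.append({**base, "z": np.nan, "p": np.nan, "r": np.nan,
                                "effect": "reference", "n_used": 0,
                                "significant": False})
            continue
        try:
            res = wilcoxon_signed_rank(ratings[c].to_numpy(), ratings[ref].to_numpy())
            wilcox_rows.append({**base, "z": res.z, "p": res.p, "r": res.r,
                                "effect": res.label, "n_used": res.n_used,
                                "significant": res.p < cfg.alpha})
        except ValueError:
            wilcox_rows.append({**base, "z": np.nan, "p": np.nan, "r": np.nan,
                                "effect": "degenerate", "n_used": 0,
                                "significant": False})
    wilcox = pd.DataFrame(wilcox_rows)
    wilcox.to_csv(out / "wilcoxon.csv", index=False, float_format="%.10g")

    # Dissimilarities between the items underlying the pair columns.
    items = sorted({x for p in parsed for x in p})
    means = pd.Series({p: float(ratings[c].mean()) for c, p in zip(cols, parsed)})
    if cfg.dissimilarity == "bray_curtis":
        dmat = bray_curtis(rating_profiles(means, items), labels=items)
    else:
        dmat = mean_difference_matrix(means, items)
    dmat.to_csv(out / "dissimilarity.csv")

    nmds_results = []
    for k in range(1, cfg.k_max + 1):
        res = nmds(dmat, k=k, seed=cfg.seed, restarts=cfg.restarts)
        nmds_results.append(
            {"k": k, "stress": res.stress, "restarts": res.restarts,
             "seed": res.seed, "coords": res.coords.tolist()}
        )
    (out / "nmds.json").write_text(json.dumps(nmds_results, indent=2, sort_keys=True))

    fractions, eigvals, negative = pcoa_scree(dmat)
    scree = {
        "fractions": fractions.tolist(),
        "eigenvalues": eigvals.tolist(),
        "negative_eigenvalues": negative.tolist(),
        "top3_fraction": float(fractions[:3].sum()) if fractions.size else 0.0,
    }
    (out / "scree.json").write_text(json.dumps(scree, indent=2, sort_keys=True))

    _write_metadata(cfg, out, {"n_subjects": int(len(ratings)), "n_pairs": len(cols)})
    return {"wilcoxon": wilcox, "dissimilarity": dmat, "nmds": nmds_results, "scree": scree}
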