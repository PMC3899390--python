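"""Procedural generation of bi-coloured striped search displays.

A display is a 1024x768 raster of eight vertical stripes in two alternating
tones.  Stripe boundaries sit on average 128 px apart with Gaussian jitter
(SD 16 px), except the display midline, which is a fixed colour boundary.
Colour-reversed squares straddling the interior boundaries create the
percept of striped foreground squares on a striped background.  A small
circular target (16 px diameter, 10% lighter than its immediate background)
is placed according to one of five treatments:

* ``Dark`` / ``Light`` - monotone target on a matching monotone stripe,
  clear of all squares.
* ``Stripe``           - two-tone target on a stripe-stripe boundary,
  clear of all squares.
* ``Square``           - two-tone target on the internal colour midline of
  a square.
* ``Border``           - two-tone target on the vertical outer edge of a
  square, i.e. the square-background border.

The three boundary treatments share identical local contrast: the two
tones immediately adjacent to the target are the same pair in each case.
Only the perceptual ownership of the boundary differs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "WIDTH",
    "HEIGHT",
    "TREATMENTS",
    "SQUARE_SIDES",
    "Palette",
    "StripeField",
    "SquareSpec",
    "TargetSpec",
    "SceneSpec",
    "SceneRegenerationRequired",
    "get_palette",
    "sample_stripe_boundaries",
    "sample_colour_order",
    "place_squares",
    "place_target",
    "generate_scene",
    "render_scene",
    "tone_map",
    "save_png",
    "save_pgm",
]

WIDTH = 1024
HEIGHT = 768
NOMINAL_INTERVAL = 128
JITTER_SD = 16.0
TARGET_DIAMETER = 16
TARGET_RADIUS = TARGET_DIAMETER // 2
N_QUADRANTS = 4
QUADRANT_HEIGHT = HEIGHT // N_QUADRANTS  # 192
SQUARE_CLEARANCE = 2  # min px between a target disc and any square
TREATMENTS = ("Dark", "Light", "Stripe", "Square", "Border")
SQUARE_SIDES = {"small": 32, "large": 64}

ColourOrder = Literal["AB_start", "BA_start"]


class SceneRegenerationRequired(RuntimeError):
    """No eligible target location exists in this scene; generate a new one."""


@dataclass(frozen=True)
class Palette:
    """Two display tones plus the target lightening factor.

    Tone A plays the role of "dark" and tone B of "light"; in the chromatic
    modes the two hues are approximately isoluminant (matched CIELab L*) and
    the dark/light labels simply index the two tones.
    """

    colour_a: tuple[float, float, float]
    colour_b: tuple[float, float, float]
    mode: Literal["achromatic", "red_green", "blue_yellow"]
    lighten_factor: float = 1.10

    def __post_init__(self) -> None:
        if self.colour_a == self.colour_b:
            raise ValueError("palette tones must differ")
        if not self.lighten_factor > 1:
            raise ValueError("lighten_factor must exceed 1")
        if self.mode == "achromatic":
            for c in (self.colour_a, self.colour_b):
                if len(set(c)) != 1:
                    raise ValueError("achromatic tones must have equal channels")

    def tone(self, index: int) -> np.ndarray:
        return np.asarray(self.colour_a if index == 0 else self.colour_b, float)


# Achromatic tones 40%/60% of max intensity: symmetric about mid-grey and a
# 10% lightening of the light tone (0.66) stays in gamut.  Chromatic pairs
# are sRGB renderings of CIELab colours matched at L* = 58 (red/green:
# a*,b* = +/-45,30-40; blue/yellow: 8,-45 / 4,55), chosen so the lightened
# targets also remain in gamut.
_PALETTES = {
    "grey": Palette((0.40, 0.40, 0.40), (0.60, 0.60, 0.60), "achromatic"),
    "red_green": Palette(
        (0.8682, 0.4058, 0.3511), (0.2762, 0.6174, 0.2538), "red_green"
    ),
    "blue_yellow": Palette(
        (0.3710, 0.5454, 0.8552), (0.6690, 0.5280, 0.1349), "blue_yellow"
    ),
}


def get_palette(name: str) -> Palette:
    """Return a named default palette (``grey``, ``red_green``, ``blue_yellow``)."""
    try:
        return _PALETTES[name]
    except KeyError:
        raise KeyError(
            f"unknown palette {name!r}; choose from {sorted(_PALETTES)}"
        ) from None


@dataclass(frozen=True)
class StripeField:
    """Interior colour-boundary positions and the left-to-right tone order."""

    boundaries: tuple[int, ...]
    colour_order: ColourOrder = "AB_start"
    nominal_interval: int = NOMINAL_INTERVAL
    jitter_sd: float = JITTER_SD

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def midline(self) -> int:
        return self.boundaries[len(self.boundaries) // 2]

    def tone_index(self, x: float) -> int:
        """Tone (0 = A, 1 = B) of the background stripe containing column x."""
        stripe = int(np.searchsorted(self.boundaries, x, side="right"))
        first = 0 if self.colour_order == "AB_start" else 1
        return (first + stripe) % 2


@dataclass(frozen=True)
class SquareSpec:
    """A colour-reversed square straddling one stripe boundary."""

    boundary_x: int
    top_y: int
    side: int
    quadrant: int

    @property
    def left(self) -> int:
        return self.boundary_x - self.side // 2

    @property
    def right(self) -> int:  # exclusive
        return self.boundary_x + self.side // 2

    @property
    def bottom(self) -> int:  # exclusive
        return self.top_y + self.side


@dataclass(frozen=True)
class TargetSpec:
    centre_x: int
    centre_y: int
    treatment: str
    diameter: int = TARGET_DIAMETER

    @property
    def split(self) -> bool:
        return self.treatment in ("Stripe", "Square", "Border")

    @property
    def screen_side(self) -> str:
        return "left" if self.centre_x < WIDTH // 2 else "right"


@dataclass(frozen=True)
class SceneSpec:
    """Complete geometric description of one search display."""

    palette: Palette
    stripe_field: StripeField
    squares: tuple[SquareSpec, ...]
    target: TargetSpec | None
    square_size_condition: str
    seed: int
    width: int = WIDTH
    height: int = HEIGHT


def sample_stripe_boundaries(
    rng: np.random.Generator,
    width: int = WIDTH,
    nominal_interval: int = NOMINAL_INTERVAL,
    jitter_sd: float = JITTER_SD,
    colour_order: ColourOrder = "AB_start",
    max_redraws: int = 1000,
) -> StripeField:
    """Draw the seven interior boundary positions.

    Boundaries are centred on multiples of ``nominal_interval`` and jittered
    by independent normal draws (SD ``jitter_sd``), rounded to whole pixels.
    The midline is a fixed design anchor and receives no jitter.  If jitter
    produces an unordered or out-of-range set, the whole set is redrawn so
    the marginal distribution of each boundary stays normal.
    """
    if nominal_interval <= 0:
        raise ValueError("nominal_interval must be positive")
    if width % nominal_interval:
        raise ValueError("width must be divisible by nominal_interval")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    n = width // nominal_interval - 1
    nominal = nominal_interval * np.arange(1, n + 1)
    mid = n // 2
    for _ in range(max_redraws):
        b = nominal + np.round(rng.normal(0.0, jitter_sd, size=n)).astype(int)
        b[mid] = nominal[mid]
        if np.all(np.diff(b) > 0) and b[0] > 0 and b[-1] < width:
            return StripeField(
                tuple(int(x) for x in b),
                colour_order=colour_order,
                nominal_interval=nominal_interval,
                jitter_sd=jitter_sd,
            )
    raise SceneRegenerationRequired("could not order stripe boundaries")


def sample_colour_order(rng: np.random.Generator) -> ColourOrder:
    """Choose the left-to-right tone order, each with probability 0.5."""
    return "AB_start" if rng.random() < 0.5 else "BA_start"


def place_squares(
    stripe_field: StripeField,
    side: int,
    rng: np.random.Generator,
    height: int = HEIGHT,
) -> tuple[SquareSpec, ...]:
    """Place four colour-reversed squares on every non-midline boundary.

    The top edge of each square sits at a uniform integer offset in
    ``[1, 192 - 2*side]`` within its vertical quadrant, which both varies the
    layout and guarantees that squares never touch.
    """
    if side not in (32, 64):
        raise ValueError("square side must be 32 or 64 px")
    quad_h = height // N_QUADRANTS
    hi = quad_h - 2 * side
    if hi < 1:
        raise ValueError("square too large for quadrant")
    squares = []
    for bx in stripe_field.boundaries:
        if bx == stripe_field.midline:
            continue
        for q in range(N_QUADRANTS):
            u = int(rng.integers(1, hi + 1))
            squares.append(SquareSpec(boundary_x=bx, top_y=q * quad_h + u, side=side, quadrant=q))
    return tuple(squares)


def tone_map(
    stripe_field: StripeField,
    squares: Sequence[SquareSpec],
    width: int = WIDTH,
    height: int = HEIGHT,
) -> np.ndarray:
    """Background tone index (0/1) per pixel, including square colour reversal."""
    cols = np.empty(width, dtype=np.int8)
    edges = (0, *stripe_field.boundaries, width)
    first = 0 if stripe_field.colour_order == "AB_start" else 1
    for i in range(len(edges) - 1):
        cols[edges[i] : edges[i + 1]] = (first + i) % 2
    tones = np.tile(cols, (height, 1))
    for sq in squares:
        tones[sq.top_y : sq.bottom, sq.left : sq.right] = (
            1 - tones[sq.top_y : sq.bottom, sq.left : sq.right]
        )
    return tones


def _square_mask(
    squares: Sequence[SquareSpec],
    clearance: int = 0,
    width: int = WIDTH,
    height: int = HEIGHT,
) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    for sq in squares:
        mask[
            max(sq.top_y - clearance, 0) : sq.bottom + clearance,
            max(sq.left - clearance, 0) : sq.right + clearance,
        ] = True
    return mask


def disc_mask(
    cx: int, cy: int, width: int = WIDTH, height: int = HEIGHT, radius: int = TARGET_RADIUS
) -> np.ndarray:
    """Boolean pixel mask of the target disc centred at grid point (cx, cy)."""
    ys, xs = np.ogrid[:height, :width]
    return (xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2 <= radius**2


def _half_ok(cx: int, width: int = WIDTH, radius: int = TARGET_RADIUS) -> bool:
    # the whole disc at least 1 px inside one screen half
    mid = width // 2
    return cx + radius <= mid - 1 or cx - radius >= mid + 1


def place_target(
    stripe_field: StripeField,
    squares: Sequence[SquareSpec],
    treatment: str,
    rng: np.random.Generator,
    width: int = WIDTH,
    height: int = HEIGHT,
    max_tries: int = 2000,
) -> TargetSpec:
    """Sample a target position uniformly over the treatment's eligible set.

    Raises :class:`SceneRegenerationRequired` when no eligible location is
    found within the retry budget, so the caller can rebuild the scene
    rather than silently accepting a biased placement.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    r = TARGET_RADIUS
    mid = width // 2

    if treatment in ("Dark", "Light"):
        want = 0 if treatment == "Dark" else 1
        tones = tone_map(stripe_field, squares, width, height)
        blocked = _square_mask(squares, clearance=SQUARE_CLEARANCE, width=width, height=height)
        ok = (tones == want) & ~blocked
        for _ in range(max_tries):
            cx = int(rng.integers(r, width - r + 1))
            cy = int(rng.integers(r, height - r + 1))
            if not _half_ok(cx, width):
                continue
            d = disc_mask(cx, cy, width, height)
            if np.all(ok[d]):
                return TargetSpec(cx, cy, treatment)
        raise SceneRegenerationRequired(f"no eligible {treatment} location")

    if treatment == "Stripe":
        # vertical segments of non-midline boundaries clear of squares
        segments: list[tuple[int, int, int]] = []  # (boundary_x, cy_lo, cy_hi)
        for bx in stripe_field.boundaries:
            if bx == stripe_field.midline or not _half_ok(bx, width):
                continue
            occupied = sorted(
                (sq.top_y - SQUARE_CLEARANCE, sq.bottom + SQUARE_CLEARANCE)
                for sq in squares
                if abs(sq.boundary_x - bx) < NOMINAL_INTERVAL // 2 + 64
                and sq.left - SQUARE_CLEARANCE < bx + r
                and sq.right + SQUARE_CLEARANCE > bx - r
            )
            lo = r
            for top, bottom in occupied:
                if top - r >= lo:
                    segments.append((bx, lo, top - r))
                lo = max(lo, bottom + r)
            if height - r >= lo:
                segments.append((bx, lo, height - r))
        lengths = np.array([hi - lo + 1 for _, lo, hi in segments], float)
        if not len(segments) or lengths.sum() <= 0:
            raise SceneRegenerationRequired("no square-free stripe boundary segment")
        i = int(rng.choice(len(segments), p=lengths / lengths.sum()))
        bx, lo, hi = segments[i]
        return TargetSpec(bx, int(rng.integers(lo, hi + 1)), treatment)

    # Square / Border: anchored to one square
    candidates = []
    for sq in squares:
        if treatment == "Square":
            xs = [sq.boundary_x]
        else:
            xs = [sq.left, sq.right]
        for cx in xs:
            if _half_ok(cx, width):
                candidates.append((sq, cx))
    if not candidates:
        raise SceneRegenerationRequired(f"no eligible {treatment} anchor")
    sq, cx = candidates[int(rng.integers(len(candidates)))]
    cy = int(rng.integers(sq.top_y + r, sq.bottom - r + 1))
    return TargetSpec(cx, cy, treatment)


def generate_scene(
    palette: Palette | str,
    square_size: str,
    treatment: str,
    seed: int,
    max_regenerations: int = 20,
) -> SceneSpec:
    """Build a full scene; regenerates the layout if target placement fails."""
    if isinstance(palette, str):
        palette = get_palette(palette)
    side = SQUARE_SIDES[square_size]
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_regenerations):
        rng = np.random.Generator(np.random.PCG64(child))
        order = sample_colour_order(rng)
        field = sample_stripe_boundaries(rng, colour_order=order)
        squares = place_squares(field, side, rng)
        try:
            target = place_target(field, squares, treatment, rng)
        except SceneRegenerationRequired:
            continue
        return SceneSpec(
            palette=palette,
            stripe_field=field,
            squares=squares,
            target=target,
            square_size_condition=square_size,
            seed=seed,
        )
    raise SceneRegenerationRequired(
        f"no eligible {treatment} placement after {max_regenerations} layouts"
    )


def render_scene(scene: SceneSpec) -> tuple[np.ndarray, dict]:
    """Rasterise a scene to a float RGB image in [0, 1] plus ground truth.

    Target pixels take the local background colour scaled by the palette's
    lighten factor, so each half of a two-tone target is lightened relative
    to its own side's tone.  Values pushed past 1.0 are clipped and flagged
    in the metadata.
    """
    tones = tone_map(scene.stripe_field, scene.squares, scene.width, scene.height)
    img = np.where(
        tones[..., None] == 0, scene.palette.tone(0), scene.palette.tone(1)
    ).astype(float)
    gamut_clipped = False
    if scene.target is not None:
        d = disc_mask(scene.target.centre_x, scene.target.centre_y, scene.width, scene.height)
        lightened = img[d] * scene.palette.lighten_factor
        if np.any(lightened > 1.0):
            gamut_clipped = True
            lightened = np.clip(lightened, 0.0, 1.0)
        img[d] = lightened
    meta = {
        "width": scene.width,
        "height": scene.height,
        "palette_mode": scene.palette.mode,
        "colour_order": scene.stripe_field.colour_order,
        "boundaries": list(scene.stripe_field.boundaries),
        "squares": [
            {"boundary_x": s.boundary_x, "top_y": s.top_y, "side": s.side, "quadrant": s.quadrant}
            for s in scene.squares
        ],
        "square_size_condition": scene.square_size_condition,
        "seed": scene.seed,
        "gamut_clipped": gamut_clipped,
    }
    if scene.target is not None:
        meta["target"] = {
            "centre_x": scene.target.centre_x,
            "centre_y": scene.target.centre_y,
            "diameter": scene.target.diameter,
            "treatment": scene.target.treatment,
            "split": scene.target.split,
        }
        meta["answer_side"] = scene.target.screen_side
    return img, meta


def save_png(img: np.ndarray, path) -> None:
    """Write a float [0,1] RGB raster as an 8-bit PNG."""
    from PIL import Image

    Image.fromarray(np.round(img * 255).astype(np.uint8), mode="RGB").save(path)


def save_pgm(img: np.ndarray, path) -> None:
    """Write an achromatic raster as an 8-bit binary PGM (grey channel only)."""
    from PIL import Image

    grey = np.round(img[..., 0] * 255).astype(np.uint8)
    Image.fromarray(grey, mode="L").save(path, format="PPM")


def strip_target(scene: SceneSpec) -> SceneSpec:
    """Return the same scene without its target (for background-only rasters)."""
    return replace(scene, target=None)
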