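"""Packaged parametric fruit shapes.

Each builder returns a :class:`~carposim.mesh.ProfileSpec` whose outer
profile runs from the blossom end (z_max) to the pedicel (z_min) in the
(radial, axial) half-plane, in cm.  The tomato shapes share one template
so that the round/elongated pair below conserves pericarp volume exactly
(both boundaries are scaled by the same volume-preserving map).
"""

from __future__ import annotations

import numpy as np

from .mesh import ProfileSpec

_N = 80


def _revolution_profile(r_of_u, z_lo: float, z_hi: float, n: int = _N) -> np.ndarray:
    zc = 0.5 * (z_lo + z_hi)
    half = 0.5 * (z_hi - z_lo)
    u = np.linspace(1.0, -1.0, n)
    z = zc + half * u
    r = np.asarray([r_of_u(ui) for ui in u])
    r[0] = r[-1] = 0.0
    return np.column_stack([r, z])


def _tomato(k_r: float = 1.0, k_z: float = 1.0, bulge: float = 0.0) -> ProfileSpec:
    """Tomato template: outer skin plus the pericarp/columella boundary.

    ``k_r``/``k_z`` scale radially/axially (k_r^2 * k_z = 1 preserves
    volume); ``bulge`` skews mass toward the blossom end (obovoid)."""

    def outer(u):
        # flattened shoulder at the stem end (p=0.25), rounded blossom end
        p = 0.25 if u < 0 else 0.47
        return 2.1 * max(1.0 - u * u, 0.0) ** p * (1.0 + bulge * u)

    def inner(u):
        # self-similar boundary: 0.66x radial, 0.69x axial about the centre
        p = 0.25 if u < 0 else 0.47
        return 0.66 * 2.1 * max(1.0 - u * u, 0.0) ** p * (1.0 + bulge * u)

    out = _revolution_profile(outer, -2.0, 2.5)
    inn = _revolution_profile(inner, 0.25 - 2.25 * 0.69, 0.25 + 2.25 * 0.69)
    for prof in (out, inn):
        prof[:, 0] *= k_r
        prof[:, 1] = 0.25 + (prof[:, 1] - 0.25) * k_z
    return ProfileSpec(
        outer_profile=out,
        inner_profiles=[inn],
        tissue_labels=["pericarp", "columella"],
    )


def tomato_round() -> ProfileSpec:
    return _tomato()


def tomato_elongated() -> ProfileSpec:
    """Elongated (San Marzano-like) tomato: long cylindrical body with a
    tapered blossom tip, radially scaled so its pericarp volume equals the
    round variety's (the inner boundary is self-similar in both, so equal
    outer volume implies equal pericarp volume)."""

    def shape(u):
        taper = 1.0 - 0.62 * max(u, 0.0) ** 1.1
        return max(1.0 - u * u, 0.0) ** 0.32 * taper

    z_lo, z_hi = -2.95, 4.0

    def outer_unit(u):
        return shape(u)

    unit = ProfileSpec(
        outer_profile=_revolution_profile(outer_unit, z_lo, z_hi),
        tissue_labels=["pericarp"],
    )
    r_scale = np.sqrt(tomato_round().swept_volume / unit.swept_volume)

    def outer(u):
        return r_scale * shape(u)

    def inner(u):
        return 0.66 * r_scale * shape(u)

    out = _revolution_profile(outer, z_lo, z_hi)
    zc = 0.5 * (z_lo + z_hi)
    half = 0.5 * (z_hi - z_lo)
    inn = _revolution_profile(inner, zc - 0.69 * half, zc + 0.69 * half)
    return ProfileSpec(
        outer_profile=out, inner_profiles=[inn], tissue_labels=["pericarp", "columella"]
    )


def tomato_obovoid() -> ProfileSpec:
    return _tomato(bulge=0.22)


def tomato_ellipsoid() -> ProfileSpec:
    spec = _tomato()

    def outer(u):
        return 2.0 * np.sqrt(max(1.0 - u * u, 0.0))

    out = _revolution_profile(outer, -2.0, 2.5)
    return ProfileSpec(
        outer_profile=out,
        inner_profiles=[p.copy() for p in spec.inner_profiles],
        tissue_labels=["pericarp", "columella"],
    )


def nectarine() -> ProfileSpec:
    """Nectarine: spherical-ish mesocarp around an ellipsoidal stone."""

    def outer(u):
        return 2.4 * np.sqrt(max(1.0 - u * u, 0.0))

    def stone(u):
        return 1.1 * np.sqrt(max(1.0 - u * u, 0.0))

    out = _revolution_profile(outer, -2.6, 2.6)
    inn = _revolution_profile(stone, -1.5, 1.5)
    return ProfileSpec(
        outer_profile=out, inner_profiles=[inn], tissue_labels=["mesocarp", "stone"]
    )


BUILTIN = {
    "tomato_round": tomato_round,
    "tomato_elongated": tomato_elongated,
    "tomato_obovoid": tomato_obovoid,
    "tomato_ellipsoid": tomato_ellipsoid,
    "nectarine": nectarine,
}


def get_profile(name: str) -> ProfileSpec:
    try:
        return BUILTIN[name]()
    except KeyError:
        raise KeyError(f"unknown builtin profile {name!r}; options: {sorted(BUILTIN)}")
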