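"""Ellipsoidal Lambert Azimuthal Equal-Area projection, ETRS89-LAEA variant.

Implements the forward and inverse oblique-aspect LAEA mapping on the GRS80
ellipsoid with the EPSG:3035 parameters (centre 10°E 52°N, false easting
4 321 000 m, false northing 3 210 000 m), following the classical formulas
(Snyder, *Map Projections — A Working Manual*, and the EPSG guidance notes).
The projection is authalic: it preserves area exactly, which is why the
pan-European statistical grids are built on it.

Only this one projection pair is provided; the package is not a CRS engine.
"""

from __future__ import annotations

import numpy as np

# GRS80 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257222101
_E2 = _F * (2.0 - _F)
_E = np.sqrt(_E2)

# EPSG:3035 projection parameters
LON_0_DEG = 10.0
LAT_0_DEG = 52.0
FALSE_EASTING = 4_321_000.0
FALSE_NORTHING = 3_210_000.0

_LAM0 = np.deg2rad(LON_0_DEG)
_PHI0 = np.deg2rad(LAT_0_DEG)


def _q(sin_phi: np.ndarray) -> np.ndarray:
    """Authalic-latitude auxiliary q(φ) of Snyder eq. 3-12."""
    es = _E * sin_phi
    return (1.0 - _E2) * (
        sin_phi / (1.0 - _E2 * sin_phi * sin_phi)
        - (1.0 / (2.0 * _E)) * np.log((1.0 - es) / (1.0 + es))
    )


_QP = float(_q(np.asarray(1.0)))          # q at the pole
_RQ = _A * np.sqrt(_QP / 2.0)             # radius of the authalic sphere
_BETA1 = np.arcsin(_q(np.asarray(np.sin(_PHI0))) / _QP)
_SINB1 = float(np.sin(_BETA1))
_COSB1 = float(np.cos(_BETA1))
_M1 = np.cos(_PHI0) / np.sqrt(1.0 - _E2 * np.sin(_PHI0) ** 2)
_D = _A * _M1 / (_RQ * _COSB1)


def wgs84_to_laea(lon, lat):
    """Project WGS84 longitude/latitude (degrees) to EPSG:3035 metres.

    Accepts scalars or arrays; returns (easting, northing) of the same shape.
    Raises ``ValueError`` on non-finite or out-of-range input.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("non-finite coordinate in input")
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude/latitude outside valid range")

    phi = np.deg2rad(lat)
    dlam = np.deg2rad(lon) - _LAM0
    beta = np.arcsin(np.clip(_q(np.sin(phi)) / _QP, -1.0, 1.0))
    sinb, cosb = np.sin(beta), np.cos(beta)
    denom = 1.0 + _SINB1 * sinb + _COSB1 * cosb * np.cos(dlam)
    b = _RQ * np.sqrt(2.0 / denom)
    x = b * _D * cosb * np.sin(dlam)
    y = (b / _D) * (_COSB1 * sinb - _SINB1 * cosb * np.cos(dlam))
    easting = FALSE_EASTING + x
    northing = FALSE_NORTHING + y
    if easting.ndim == 0:
        return float(easting), float(northing)
    return easting, northing


def laea_to_wgs84(easting, northing):
    """Inverse-project EPSG:3035 metres back to WGS84 degrees.

    Round-trips with :func:`wgs84_to_laea` to well below 1e-9 degrees over
    the projection's useful domain.
    """
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not (np.all(np.isfinite(easting)) and np.all(np.isfinite(northing))):
        raise ValueError("non-finite coordinate in input")

    x = easting - FALSE_EASTING
    y = northing - FALSE_NORTHING
    rho = np.hypot(x / _D, _D * y)
    # avoid 0/0 at the projection centre; the centre maps to (lon0, lat0)
    rho_safe = np.where(rho == 0.0, 1.0, rho)
    ce = 2.0 * np.arcsin(np.clip(rho / (2.0 * _RQ), -1.0, 1.0))
    sin_ce, cos_ce = np.sin(ce), np.cos(ce)
    q = _QP * (cos_ce * _SINB1 + _D * y * sin_ce * _COSB1 / rho_safe)
    lam = _LAM0 + np.arctan2(
        x * sin_ce,
        _D * rho_safe * _COSB1 * cos_ce - _D * _D * y * _SINB1 * sin_ce,
    )

    # latitude from q by fixed-point iteration (Snyder eq. 3-16)
    phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
    for _ in range(30):
        sin_phi = np.sin(phi)
        es = _E * sin_phi
        one = 1.0 - _E2 * sin_phi * sin_phi
        corr = (one * one / (2.0 * np.cos(phi))) * (
            q / (1.0 - _E2)
            - sin_phi / one
            + (1.0 / (2.0 * _E)) * np.log((1.0 - es) / (1.0 + es))
        )
        phi = phi + corr
        if np.all(np.abs(corr) < 1e-14):
            break

    lon = np.rad2deg(np.where(rho == 0.0, _LAM0, lam))
    lat = np.rad2deg(np.where(rho == 0.0, _PHI0, phi))
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat
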