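"""Synthetic two-gyre lagoon circulation on a rectilinear grid.

A desk-scale stand-in for a full 3-D hydrodynamic model, built so the
features that drive larval connectivity survive: two counter-posed
circulation cells (northeast and southwest), a weak persistent westward
drift (trade-wind forced), wind modulation of the gyre strength, and a
multiplicative vertical shear profile.

Velocities derive from a streamfunction (u = dpsi/dy, v = -dpsi/dx by
centered differences), so the discrete divergence of the stored field
vanishes identically off the land mask.  The streamfunction is tapered to
zero within one cell of land, which makes land-node velocities exactly zero
without breaking the divergence identity.  The field is linear in the wind
modulation, and is stored compactly as base gyre fields plus hourly
amplitude series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["FlowConfig", "FlowField", "build_flow_field", "sample_velocity", "uniform_flow_field"]


@dataclass
class FlowConfig:
    nx: int = 117
    ny: int = 59
    cell_size: float = 100.0  # m
    lagoon_semi_axes: tuple[float, float] = (5600.0, 2700.0)  # ellipse a, b (m)
    n_hours: int = 24 * 40
    gyre_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (2400.0, 800.0),  # NE cell
        (-2400.0, -800.0),  # SW cell
    )
    gyre_sigma: float = 1600.0  # m
    gyre_psi0: float = 250.0  # m^2/s, opposite signs per lobe
    drift_speed: float = 0.03  # m/s westward (negative x)
    wind_base_speed: float = 6.0  # m/s easterly trades
    wind_diel_amplitude: float = 1.0  # m/s diel breathing
    wind_event_rate_per_day: float = 0.1  # seeded episodic events
    wind_event_amplitude: float = 3.0  # m/s
    wind_direction_deg: float = 90.0  # blowing from the east
    speed_cap: float = 1.0  # m/s
    shear_surface: float = 1.0
    shear_slope_per_m: float = 0.02
    shear_min: float = 0.3
    depth_max: float = 40.0  # m
    seed: int = 0


@dataclass
class FlowField:
    """Low-rank, divergence-free flow: u(t) = amp(t) * u_gyre + u_drift."""

    x: np.ndarray  # (nx,) node coordinates, m
    y: np.ndarray  # (ny,)
    mask: np.ndarray  # (ny, nx) True on land
    times: np.ndarray  # hourly stamps, h
    u_gyre: np.ndarray  # (ny, nx)
    v_gyre: np.ndarray
    u_drift: np.ndarray
    v_drift: np.ndarray
    amplitudes: np.ndarray  # (n_times,) wind modulation factor
    wind_speed: np.ndarray  # (n_times,) m/s
    wind_direction_deg: float
    config: FlowConfig = field(repr=False, default=None)

    # ------------------------------------------------------------------
    @property
    def cell_size(self) -> float:
        return float(self.x[1] - self.x[0])

    def shear_factor(self, depth: np.ndarray | float) -> np.ndarray:
        c = self.config
        return np.maximum(c.shear_min, c.shear_surface - c.shear_slope_per_m * np.asarray(depth, float))

    def velocity_grid(self, t_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Full (u, v) node fields at a stored time index."""
        a = self.amplitudes[t_index]
        return a * self.u_gyre + self.u_drift, a * self.v_gyre + self.v_drift

    def discrete_divergence(self, t_index: int) -> np.ndarray:
        """Centered-difference divergence at interior nodes (ny-2, nx-2)."""
        u, v = self.velocity_grid(t_index)
        d = self.cell_size
        dudx = (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * d)
        dvdy = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2 * d)
        return dudx + dvdy

    def in_domain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        inside = (
            (x >= self.x[0])
            & (x <= self.x[-1])
            & (y >= self.y[0])
            & (y <= self.y[-1])
        )
        out = np.zeros_like(inside)
        if inside.any():
            ix = np.clip(np.round((x - self.x[0]) / self.cell_size).astype(int), 0, len(self.x) - 1)
            iy = np.clip(np.round((y - self.y[0]) / self.cell_size).astype(int), 0, len(self.y) - 1)
            out = inside & ~self.mask[iy, ix]
        return out

    # ------------------------------------------------------------------
    def to_dataset(self):
        import xarray as xr

        return xr.Dataset(
            data_vars=dict(
                u_gyre=(("y", "x"), self.u_gyre),
                v_gyre=(("y", "x"), self.v_gyre),
                u_drift=(("y", "x"), self.u_drift),
                v_drift=(("y", "x"), self.v_drift),
                mask=(("y", "x"), self.mask.astype(np.int8)),
                amplitude=(("time",), self.amplitudes),
                wind_speed=(("time",), self.wind_speed),
            ),
            coords=dict(x=self.x, y=self.y, time=self.times),
            attrs=dict(wind_direction_deg=self.wind_direction_deg),
        )

    def to_netcdf(self, path: str) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


# ----------------------------------------------------------------------

def _wind_series(config: FlowConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(config.n_hours + 1, dtype=float)
    speed = config.wind_base_speed + config.wind_diel_amplitude * np.sin(2 * np.pi * t / 24.0)
    # seeded episodic wind events: square pulses of 12-48 h
    n_events = rng.poisson(config.wind_event_rate_per_day * config.n_hours / 24.0)
    for _ in range(n_events):
        start = rng.integers(0, config.n_hours)
        dur = rng.integers(12, 49)
        speed[start : start + dur] += rng.uniform(-1, 1) * config.wind_event_amplitude
    return np.maximum(speed, 0.0)


def _psi_to_uv(psi: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
    u = np.zeros_like(psi)
    v = np.zeros_like(psi)
    u[1:-1, :] = (psi[2:, :] - psi[:-2, :]) / (2 * d)
    v[:, 1:-1] = -(psi[:, 2:] - psi[:, :-2]) / (2 * d)
    return u, v


def build_flow_field(config: FlowConfig | None = None) -> FlowField:
    """Assemble the two-gyre + drift field with a seeded wind series.

    The gyre lobes are Gaussian streamfunction bumps of opposite sign whose
    amplitude follows ``wind_speed(t) / wind_base_speed``; the westward
    drift is steady.  Velocities are capped by rescaling (with a warning) if
    the configured maximum is exceeded.
    """
    config = config or FlowConfig()
    rng = np.random.default_rng(config.seed)
    nx, ny, d = config.nx, config.ny, config.cell_size
    x = (np.arange(nx) - (nx - 1) / 2) * d
    y = (np.arange(ny) - (ny - 1) / 2) * d
    xx, yy = np.meshgrid(x, y)

    a, b = config.lagoon_semi_axes
    water = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    mask = ~water

    # taper: exactly zero within one cell of land, smooth ramp beyond
    if mask.any():
        dist = ndimage.distance_transform_edt(water)  # cells to nearest land
        ramp = np.clip((dist - 1.0) / 3.0, 0.0, 1.0)
        taper = ramp * ramp * (3 - 2 * ramp)  # smoothstep
    else:
        taper = np.ones_like(xx)

    (cx1, cy1), (cx2, cy2) = config.gyre_centers
    s2 = 2.0 * config.gyre_sigma**2
    psi_gyre = config.gyre_psi0 * (
        np.exp(-((xx - cx1) ** 2 + (yy - cy1) ** 2) / s2)
        - np.exp(-((xx - cx2) ** 2 + (yy - cy2) ** 2) / s2)
    )
    psi_gyre *= taper
    u_gyre, v_gyre = _psi_to_uv(psi_gyre, d)

    psi_drift = -config.drift_speed * yy * taper
    u_drift, v_drift = _psi_to_uv(psi_drift, d)

    wind = _wind_series(config, rng)
    amplitudes = wind / config.wind_base_speed

    vmax = np.max(
        np.hypot(
            amplitudes.max() * u_gyre + u_drift, amplitudes.max() * v_gyre + v_drift
        )
    )
    if vmax > config.speed_cap:
        scale = config.speed_cap / vmax
        warnings.warn(
            f"velocity cap exceeded ({vmax:.2f} m/s); amplitudes rescaled by {scale:.3f}"
        )
        u_gyre *= scale
        v_gyre *= scale
        u_drift *= scale
        v_drift *= scale

    return FlowField(
        x=x,
        y=y,
        mask=mask,
        times=np.arange(config.n_hours + 1, dtype=float),
        u_gyre=u_gyre,
        v_gyre=v_gyre,
        u_drift=u_drift,
        v_drift=v_drift,
        amplitudes=amplitudes,
        wind_speed=wind,
        wind_direction_deg=config.wind_direction_deg,
        config=config,
    )


def uniform_flow_field(
    u: float,
    v: float = 0.0,
    nx: int = 41,
    ny: int = 21,
    cell_size: float = 100.0,
    n_hours: int = 48,
) -> FlowField:
    """All-water constant-velocity field (testing and kinematics checks)."""
    config = FlowConfig(
        nx=nx,
        ny=ny,
        cell_size=cell_size,
        n_hours=n_hours,
        lagoon_semi_axes=(1e12, 1e12),  # no land
        gyre_psi0=0.0,
        drift_speed=0.0,
        wind_diel_amplitude=0.0,
        wind_event_rate_per_day=0.0,
        shear_slope_per_m=0.0,
    )
    field_ = build_flow_field(config)
    field_.u_drift[:] = u
    field_.v_drift[:] = v
    return field_


# ----------------------------------------------------------------------

def sample_velocity(
    field: FlowField,
    x: np.ndarray | float,
    y: np.ndarray | float,
    depth: np.ndarray | float,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity at points: bilinear in space, linear in time, sheared by depth.

    Points on the land mask return (0, 0); ``t`` outside the stored window
    raises.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    eps = 1e-6  # tolerate float accumulation at the window edges
    if t < field.times[0] - eps or t > field.times[-1] + eps:
        raise ValueError(f"time {t} outside the flow window")
    t = min(max(t, field.times[0]), field.times[-1])

    # time interpolation reduces to interpolating the amplitude (linearity)
    amp = float(np.interp(t, field.times, field.amplitudes))

    d = field.cell_size
    fx = np.clip((x - field.x[0]) / d, 0, len(field.x) - 1 - 1e-9)
    fy = np.clip((y - field.y[0]) / d, 0, len(field.y) - 1 - 1e-9)
    ix = fx.astype(int)
    iy = fy.astype(int)
    tx = fx - ix
    ty = fy - iy

    def _bilin(f: np.ndarray) -> np.ndarray:
        return (
            f[iy, ix] * (1 - tx) * (1 - ty)
            + f[iy, ix + 1] * tx * (1 - ty)
            + f[iy + 1, ix] * (1 - tx) * ty
            + f[iy + 1, ix + 1] * tx * ty
        )

    u = amp * _bilin(field.u_gyre) + _bilin(field.u_drift)
    v = amp * _bilin(field.v_gyre) + _bilin(field.v_drift)

    shear = field.shear_factor(depth)
    u = u * shear
    v = v * shear

    on_land = field.mask[np.round(fy).astype(int), np.round(fx).astype(int)]
    u = np.where(on_land, 0.0, u)
    v = np.where(on_land, 0.0, v)
    return u, v
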