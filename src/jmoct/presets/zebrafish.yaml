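# Cartoon zebrafish phantom layouts.
#
# Geometry is a deliberately simple layered/ellipsoidal stand-in for a
# juvenile fish cross-section: a water bath on top, a skin layer, bulk
# skeletal muscle, a spinal-cord cylinder running along y, a gill block at
# small x, a flow vessel, and a small pigmented (depolarizing) patch near the
# surface.  Depth axis is z (tissue pixels of 7.24 um).
#
# Per-organ attenuation (mm^-1) and birefringence values are organ-scale
# reference means for wild-type zebrafish at two ages; they are the simulation
# ground truth that the estimators are expected to recover.

juvenile:
  description: full-size layered cartoon of a juvenile zebrafish section
  shape: [256, 96, 64]
  geometry:
    water_top: 20
    skin_thickness: 10
    spine: {z_center: 84, x_center: 48, rz: 16, rx: 14}
    gills: {x_max: 20, z_max: 110}
    vessel: {z_center: 52, x_center: 76, radius: 4}
    pigment: {x_min: 82, z_min: 30, z_max: 42}
  system:
    depth_pixels: 256
    x_pixels: 96
    y_pixels: 64
    noise_floor_db: -45.0
    n_repeats: 4

juvenile-mini:
  description: reduced-size variant of the juvenile layout for quick runs
  shape: [160, 48, 32]
  geometry:
    water_top: 12
    skin_thickness: 8
    spine: {z_center: 60, x_center: 24, rz: 11, rx: 9}
    gills: {x_max: 10, z_max: 70}
    vessel: {z_center: 40, x_center: 38, radius: 3}
    pigment: {x_min: 42, z_min: 22, z_max: 32}
  system:
    depth_pixels: 160
    x_pixels: 48
    y_pixels: 32
    noise_floor_db: -45.0
    n_repeats: 4

# organ optical properties shared by all layouts
#
# Reflectivity (backscatter weight) is tied to attenuation through a constant
# albedo scale: the depth-resolved attenuation estimator assumes the
# backscattered fraction is proportional to the local attenuation
# coefficient, and the phantom emulates scattering-dominated tissue for which
# that assumption holds.
optics:
  albedo_scale: 0.2
  static:
    water:   {mu: 0.1, birefringence: 0.0, axis: 0.0}
    vessel:  {mu: 1.0, birefringence: 0.0, axis: 0.0, flow: true}
    pigment: {mu: 5.0, birefringence: 0.0, axis: 0.0, depol_fraction: 0.8}
  axes: {spine: 0.0, muscles: 0.6, gills: 1.1, skin: 0.3}
  by_age:
    1-month:
      spine:   {mu: 11.6, birefringence: 1.2e-3}
      muscles: {mu: 0.5,  birefringence: 1.6e-3}
      gills:   {mu: 2.9,  birefringence: 0.9e-3}
      skin:    {mu: 5.7,  birefringence: 1.5e-3}
    2-month:
      spine:   {mu: 6.8,  birefringence: 2.2e-3}
      muscles: {mu: 0.6,  birefringence: 1.8e-3}
      gills:   {mu: 2.0,  birefringence: 0.9e-3}
      skin:    {mu: 4.0,  birefringence: 1.4e-3}
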