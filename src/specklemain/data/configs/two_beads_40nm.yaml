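# Two touching beads at 40 nm centre-to-centre, 100x/1.5 oil detection,
# blind-SIM at 4x upsampling (~16 nm reconstruction pixel), 200 frames.
scene_kind: two_beads
separation: 40.0
bead_diameter: 46.0

lambda_exc: 488.0
na_inc: 0.2
n_modes: 100
roughness_rms: 1.1
roughness_corr_length: 35.0
z_speckle: 10.0

na_det: 1.5
lambda_em: 520.0
camera_pixel: 65.0
n_camera_px: 16
dx_f: 5.0
n_frames: 200
photons_per_emitter: 5000.0
background: 5.0
read_sd: 2.0

upsample: 4
max_iter: 800
tol: 1.0e-6

master_seed: 1
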