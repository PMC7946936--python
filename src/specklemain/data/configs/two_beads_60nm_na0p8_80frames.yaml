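# Two beads at 60 nm centre-to-centre resolved from only 80 sub-frames
# with a 0.8-NA detection objective.
scene_kind: two_beads
separation: 60.0
bead_diameter: 46.0

lambda_exc: 488.0
na_inc: 0.2
n_modes: 100
roughness_rms: 1.1
roughness_corr_length: 35.0
z_speckle: 10.0

na_det: 0.8
lambda_em: 520.0
camera_pixel: 65.0
n_camera_px: 16
dx_f: 5.0
n_frames: 80
photons_per_emitter: 5000.0
background: 5.0
read_sd: 2.0

upsample: 3
max_iter: 600
tol: 1.0e-6

master_seed: 1
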