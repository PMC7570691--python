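# limotrack

Real-time human pose tracking by fusing two scanning lidars with ten
body-worn IMUs — reimplemented as a tested Python library and CLI, with a
synthetic sensor simulator standing in for live hardware.

The pipeline:

1. **Calibration** — a ceiling lidar compares a user-free *reference*
   cloud against a *full-body* cloud (voxel change detection), finds the
   ground point and floor slope, and estimates the user's height.
2. **Skeleton construction** — a 16-joint / 15-segment kinematic tree is
   parameterized from the height via head-unit proportions
   (head unit = height / 7.5).
3. **IMU kinematics** — per-segment unit quaternions are aligned against
   the frame-0 attention pose (cancelling mounting offsets), rotated
   rest-pose bone vectors update joint positions bottom-up from the
   stance foot to the pelvis and then top-down to the whole body.
4. **Lidar leg tracking** — the lower-leg clusters of each real-time
   cloud are tracked with per-leg ground-plane particle filters; cluster
   surface returns are corrected onto the limb axis before the ankle is
   extrapolated to the floor.
5. **Fusion** — lidar foot positions (linearly resampled to the 60 Hz IMU
   grid) rigidly correct the displacement drift of the dead-reckoned pose
   within a 10 cm threshold (snap beyond it, proportional blend inside).

## Layout

| module | role |
| --- | --- |
| `limotrack.skeleton` | kinematic tree, proportions, attention pose |
| `limotrack.clouds` | change detection, ground point, slope, height |
| `limotrack.kinematics` | quaternion math, alignment, chain updates |
| `limotrack.legtrack` | leg clustering + particle-filter foot tracking |
| `limotrack.fusion` | timeline resampling, stance selection, drift correction, main loop |
| `limotrack.simulate` | synthetic sessions: motion, lidar raycasts, IMU streams, drift injection |
| `limotrack.evaluate` | joint position error, inter-segment angles, window summaries |
| `limotrack.io` / `limotrack.cli` | PCD/PLY, CSV, YAML, BVH; command line |

## CLI

```bash
# generate a synthetic capture session (clouds + IMU CSV + ground truth)
limotrack simulate --kind walk --duration 10 --height 1.75 --seed 1 --out session/

# estimate height and build a skeleton from calibration clouds (L1 frame)
limotrack calibrate --reference ref.pcd --full-cloud full.pcd --slope-source floor

# run the fused tracker on a session directory
limotrack track --config session/session.yaml --out track.csv

# score a track against ground truth
limotrack evaluate --estimated track.csv --truth session/ground_truth.csv

# export to BVH for any standard motion-capture viewer
limotrack export-bvh --track track.csv --height 1.75 --out motion.bvh
```

## Conventions

* World frame: +z up, +x forward; meters internally, centimeters only in
  reports. The ceiling lidar's L1 frame has +y pointing down at the
  floor, so the ground point carries the maximal y coordinate.
* Quaternions: Hamilton product, scalar-first `(qw, qx, qy, qz)`,
  active rotations; streams are sign-continuized on ingest.
* All stochastic code takes explicit seeds; sessions are bit-reproducible
  from `(config, seed)`.
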