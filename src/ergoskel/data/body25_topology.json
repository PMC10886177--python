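{
  "version": 1,
  "keypoint_names": [
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel"
  ],
  "links": [
    [1, 8],
    [1, 2], [2, 3], [3, 4],
    [1, 5], [5, 6], [6, 7],
    [8, 9], [9, 10], [10, 11],
    [8, 12], [12, 13], [13, 14],
    [1, 0], [0, 15], [15, 17], [0, 16], [16, 18],
    [11, 22], [22, 23], [11, 24],
    [14, 19], [19, 20], [14, 21]
  ]
}
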