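method,shot,class_id,ap
YOLO11-FSOD,3,0,82.5
YOLO11-FSOD,5,0,84.4
YOLO11-FSOD,10,0,87
TFA,3,0,96
TFA,5,0,96
TFA,10,0,95.8
VFA,3,0,90.2
VFA,5,0,97.9
VFA,10,0,90.4
FSCE,3,0,91.7
FSCE,5,0,92.1
FSCE,10,0,92
OURS,3,0,90.7
OURS,5,0,89.8
OURS,10,0,96.2
YOLO11-FSOD,3,48,59.6
YOLO11-FSOD,5,48,61.2
YOLO11-FSOD,10,48,57.9
TFA,3,48,68.5
TFA,5,48,69
TFA,10,48,69.8
VFA,3,48,63.4
VFA,5,48,67
VFA,10,48,69.2
FSCE,3,48,65.6
FSCE,5,48,68
FSCE,10,48,66.6
OURS,3,48,67
OURS,5,48,66.7
OURS,10,48,63.6
YOLO11-FSOD,3,14,83
YOLO11-FSOD,5,14,89.7
YOLO11-FSOD,10,14,86.2
TFA,3,14,95.4
TFA,5,14,92.9
TFA,10,14,89.5
VFA,3,14,88.4
VFA,5,14,88.7
VFA,10,14,88.5
FSCE,3,14,95.9
FSCE,5,14,94.5
FSCE,10,14,88
OURS,3,14,89.2
OURS,5,14,87.7
OURS,10,14,88.3
YOLO11-FSOD,3,99,80.8
YOLO11-FSOD,5,99,75.3
YOLO11-FSOD,10,99,68.9
TFA,3,99,85.2
TFA,5,99,85
TFA,10,99,84.8
VFA,3,99,86.8
VFA,5,99,88.2
VFA,10,99,89.1
FSCE,3,99,75.4
FSCE,5,99,77.5
FSCE,10,99,82.5
OURS,3,99,78.4
OURS,5,99,81.7
OURS,10,99,76.7
YOLO11-FSOD,3,3,85.9
YOLO11-FSOD,5,3,77
YOLO11-FSOD,10,3,79.3
TFA,3,3,69.6
TFA,5,3,71.3
TFA,10,3,71.4
VFA,3,3,72.6
VFA,5,3,77.4
VFA,10,3,75
FSCE,3,3,66.3
FSCE,5,3,74.3
FSCE,10,3,71.5
OURS,3,3,69.9
OURS,5,3,76.1
OURS,10,3,80.3
YOLO11-FSOD,3,21,77.6
YOLO11-FSOD,5,21,80.5
YOLO11-FSOD,10,21,83.8
TFA,3,21,89
TFA,5,21,88.8
TFA,10,21,88.8
VFA,3,21,74.7
VFA,5,21,72.8
VFA,10,21,73.7
FSCE,3,21,85.3
FSCE,5,21,80.9
FSCE,10,21,81
OURS,3,21,87.8
OURS,5,21,87.3
OURS,10,21,86.7
YOLO11-FSOD,3,39,84.8
YOLO11-FSOD,5,39,76.4
YOLO11-FSOD,10,39,79.6
TFA,3,39,88
TFA,5,39,88
TFA,10,39,93.3
VFA,3,39,88.2
VFA,5,39,88.4
VFA,10,39,89.3
FSCE,3,39,83.8
FSCE,5,39,85.7
FSCE,10,39,86.6
OURS,3,39,89.8
OURS,5,39,89.1
OURS,10,39,89.3
YOLO11-FSOD,3,66,95.1
YOLO11-FSOD,5,66,96.4
YOLO11-FSOD,10,66,97.8
TFA,3,66,89.7
TFA,5,66,90
TFA,10,66,89.9
VFA,3,66,89.1
VFA,5,66,89.1
VFA,10,66,89.1
FSCE,3,66,92.9
FSCE,5,66,93.5
FSCE,10,66,89.9
OURS,3,66,94.9
OURS,5,66,90.4
OURS,10,66,90.7
YOLO11-FSOD,3,16,67.2
YOLO11-FSOD,5,16,72.8
YOLO11-FSOD,10,16,68.9
TFA,3,16,84.3
TFA,5,16,84.4
TFA,10,16,80.9
VFA,3,16,67.7
VFA,5,16,66.5
VFA,10,16,70.7
FSCE,3,16,78.8
FSCE,5,16,80.2
FSCE,10,16,79.4
OURS,3,16,81.4
OURS,5,16,79.3
OURS,10,16,83.8
YOLO11-FSOD,3,37,79.2
YOLO11-FSOD,5,37,77.4
YOLO11-FSOD,10,37,71.8
TFA,3,37,99.4
TFA,5,37,99.3
TFA,10,37,97.8
VFA,3,37,88
VFA,5,37,88.1
VFA,10,37,88.4
FSCE,3,37,89
FSCE,5,37,89.6
FSCE,10,37,93.8
OURS,3,37,88.9
OURS,5,37,89.1
OURS,10,37,90.4
YOLO11-FSOD,3,50,82.8
YOLO11-FSOD,5,50,73.8
YOLO11-FSOD,10,50,80.7
TFA,3,50,85.1
TFA,5,50,85.5
TFA,10,50,86.1
VFA,3,50,86.5
VFA,5,50,87.4
VFA,10,50,88.1
FSCE,3,50,83
FSCE,5,50,84.1
FSCE,10,50,84.5
OURS,3,50,83.8
OURS,5,50,79.1
OURS,10,50,85.9
YOLO11-FSOD,3,26,80.7
YOLO11-FSOD,5,26,80
YOLO11-FSOD,10,26,81.6
TFA,3,26,84.6
TFA,5,26,83.7
TFA,10,26,83.1
VFA,3,26,66.6
VFA,5,26,71.6
VFA,10,26,78.6
FSCE,3,26,80.3
FSCE,5,26,77.7
FSCE,10,26,78.8
OURS,3,26,84.8
OURS,5,26,80.4
OURS,10,26,85.7
YOLO11-FSOD,3,25,82.8
YOLO11-FSOD,5,25,83.3
YOLO11-FSOD,10,25,86.4
TFA,3,25,89
TFA,5,25,89.3
TFA,10,25,89.2
VFA,3,25,81.8
VFA,5,25,84.6
VFA,10,25,88.8
FSCE,3,25,89.2
FSCE,5,25,89.3
FSCE,10,25,88.4
OURS,3,25,87.9
OURS,5,25,88.6
OURS,10,25,90.5
YOLO11-FSOD,3,70,63.2
YOLO11-FSOD,5,70,54.4
YOLO11-FSOD,10,70,57.9
TFA,3,70,67.8
TFA,5,70,67.7
TFA,10,70,66.1
VFA,3,70,52.8
VFA,5,70,59.3
VFA,10,70,66.2
FSCE,3,70,68.8
FSCE,5,70,73.2
FSCE,10,70,71.5
OURS,3,70,73.6
OURS,5,70,70.6
OURS,10,70,62.8
YOLO11-FSOD,3,24,85.8
YOLO11-FSOD,5,24,75.4
YOLO11-FSOD,10,24,79.5
TFA,3,24,87.6
TFA,5,24,86.7
TFA,10,24,87.7
VFA,3,24,84.9
VFA,5,24,84.5
VFA,10,24,84.5
FSCE,3,24,78.4
FSCE,5,24,76.5
FSCE,10,24,83.8
OURS,3,24,84.8
OURS,5,24,84.1
OURS,10,24,85.7
YOLO11-FSOD,3,67,72.7
YOLO11-FSOD,5,67,98.2
YOLO11-FSOD,10,67,98.5
TFA,3,67,81.8
TFA,5,67,82.7
TFA,10,67,83.3
VFA,3,67,92.1
VFA,5,67,94
VFA,10,67,96.5
FSCE,3,67,90.9
FSCE,5,67,90.1
FSCE,10,67,94.4
OURS,3,67,90.9
OURS,5,67,95
OURS,10,67,97.6
YOLO11-FSOD,3,101,63.9
YOLO11-FSOD,5,101,81.6
YOLO11-FSOD,10,101,88.8
TFA,3,101,17
TFA,5,101,25.7
TFA,10,101,49
VFA,3,101,38.5
VFA,5,101,55.3
VFA,10,101,67.7
FSCE,3,101,18.7
FSCE,5,101,36.9
FSCE,10,101,66.7
OURS,3,101,35.9
OURS,5,101,65
OURS,10,101,82.5
YOLO11-FSOD,3,76,17.3
YOLO11-FSOD,5,76,23.8
YOLO11-FSOD,10,76,36.8
TFA,3,76,12
TFA,5,76,27.8
TFA,10,76,28.8
VFA,3,76,17.2
VFA,5,76,28.8
VFA,10,76,33.7
FSCE,3,76,28.3
FSCE,5,76,33.1
FSCE,10,76,34.6
OURS,3,76,30.1
OURS,5,76,36.8
OURS,10,76,44.9
YOLO11-FSOD,3,15,51.4
YOLO11-FSOD,5,15,85.9
YOLO11-FSOD,10,15,89.4
TFA,3,15,65
TFA,5,15,64.8
TFA,10,15,75.2
VFA,3,15,66.6
VFA,5,15,83.2
VFA,10,15,88.3
FSCE,3,15,68.9
FSCE,5,15,79.8
FSCE,10,15,89.7
OURS,3,15,69
OURS,5,15,77.9
OURS,10,15,87.7
YOLO11-FSOD,3,95,60.5
YOLO11-FSOD,5,95,79.3
YOLO11-FSOD,10,95,72.4
TFA,3,95,51.2
TFA,5,95,58.6
TFA,10,95,64.4
VFA,3,95,42.5
VFA,5,95,38.4
VFA,10,95,57.4
FSCE,3,95,67.5
FSCE,5,95,68.1
FSCE,10,95,72.8
OURS,3,95,74.1
OURS,5,95,76.1
OURS,10,95,83.5
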