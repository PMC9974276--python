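experiment,scheme,image,TP,FN,TN,FP,AC,PR,SE,SP,FS
backbone_softmax,AlexNet,with_skull,93,5,94,8,93.50,92.08,94.90,92.16,93.47
backbone_softmax,VGG16,with_skull,94,5,95,6,94.50,94.00,94.95,94.06,94.47
backbone_softmax,VGG19,with_skull,94,7,94,5,94.00,94.95,93.07,94.95,94.00
backbone_softmax,ResNet18,with_skull,93,8,95,4,94.00,95.88,92.08,95.96,93.94
backbone_softmax,ResNet50,with_skull,94,5,94,7,94.00,93.07,94.95,93.07,94.00
fused_classifier,SM,with_skull,95,5,97,3,96.00,96.94,95.00,97.00,95.96
fused_classifier,DT,with_skull,97,5,97,1,97.00,98.98,95.10,98.98,97.00
fused_classifier,RF,with_skull,98,2,99,1,98.50,98.99,98.00,99.00,98.49
fused_classifier,NB,with_skull,98,3,95,4,96.50,96.08,97.03,95.96,96.55
fused_classifier,KNN,with_skull,97,4,96,3,96.50,97.00,96.04,96.97,96.52
fused_classifier,SVM-L,with_skull,97,2,97,4,97.00,96.04,97.98,96.04,97.00
fused_classifier,SVM-RBF,with_skull,96,5,97,2,96.50,97.96,95.05,97.98,96.48
fused_classifier,SM,without_skull,95,3,96,6,95.50,94.06,96.94,94.12,95.48
fused_classifier,DT,without_skull,97,3,96,4,96.50,96.04,97.00,96.00,96.52
fused_classifier,RF,without_skull,96,5,98,1,97.00,98.97,95.05,98.99,96.97
fused_classifier,NB,without_skull,97,4,96,3,96.50,97.00,96.04,96.97,96.52
fused_classifier,KNN,without_skull,99,2,98,1,98.50,99.00,98.02,98.99,98.51
fused_classifier,SVM-L,without_skull,98,2,97,3,97.50,97.03,98.00,97.00,97.51
fused_classifier,SVM-RBF,without_skull,97,2,97,4,97.00,96.04,97.98,96.04,97.00
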