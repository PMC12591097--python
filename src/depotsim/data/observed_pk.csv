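label,metric,value,units,source
arl_im_400,cmax,97.39,ng/mL,published clinical mean PK; single-dose 400 mg-eq IM aripiprazole lauroxil suspension
arl_im_400,auc0t,138100,ng*h/mL,published clinical mean PK; single-dose 400 mg-eq IM aripiprazole lauroxil suspension
arl_im_400,tmax,723.26,h,published clinical mean PK; single-dose 400 mg-eq IM aripiprazole lauroxil suspension
arl_im_300,cmax,87.61,ng/mL,published clinical mean PK; single-dose 300 mg-eq IM aripiprazole lauroxil suspension
arl_im_300,auc0t,91910,ng*h/mL,published clinical mean PK; single-dose 300 mg-eq IM aripiprazole lauroxil suspension
arl_im_300,tmax,1058.2,h,published clinical mean PK; single-dose 300 mg-eq IM aripiprazole lauroxil suspension
arl_im_150,cmax,40.66,ng/mL,published clinical mean PK; single-dose 150 mg-eq IM aripiprazole lauroxil suspension
arl_im_150,auc0t,52810,ng*h/mL,published clinical mean PK; single-dose 150 mg-eq IM aripiprazole lauroxil suspension
arl_im_150,tmax,1081.9,h,published clinical mean PK; single-dose 150 mg-eq IM aripiprazole lauroxil suspension
ar_im_solution_5mg,cmax,20.6,ng/mL,published clinical mean PK; 5 mg aripiprazole IM solution (gluteal)
ar_im_solution_5mg,auc0t,1423.2,ng*h/mL,published clinical mean PK; 5 mg aripiprazole IM solution (gluteal)
ar_im_solution_5mg,tmax,3.0,h,published clinical mean PK; 5 mg aripiprazole IM solution (average of individual Tmax)
ar_iv_2mg,cmax,16.71,ng/mL,published clinical mean PK; 2 mg aripiprazole IV infusion
ar_iv_2mg,auc0t,522.16,ng*h/mL,published clinical mean PK; 2 mg aripiprazole IV infusion
ar_iv_2mg,tmax,0.5,h,nominal end of infusion (infusion duration not reported)
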